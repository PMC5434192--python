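"""End-to-end synthetic pipeline tying the analysis stages together.

``run_pipeline`` simulates a two-arm longitudinal cohort (visit table,
per-region outcomes, behavioural score, per-visit scans with motion),
then runs the full analysis chain: scrubbing / trimming / Fisher-z
connectivity / edge standardization, per-region piecewise mixed models
with their contrast tables, bootstrap-calibrated network statistics,
post hoc single-subject classification and effect sizes, the demographic
battery on the bundled reference tables, brain-behaviour association, and
network-pair geometry of any significant component.  Every artifact is a
TSV or JSON file under the output directory; a QA report logs each
exclusion with the rule that fired.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference
from .behavior import (
    behavior_lme,
    fisher_exact,
    likelihood_ratio_chisq,
    two_sample_t_from_summary,
)
from .cohort import CohortParams, SpikeParams, generate_cohort, generate_scan
from .connectivity import (
    QAError,
    apply_mask,
    compute_connectivity,
    scrub_frames,
    standardize_edges,
    trim_to_common_length,
)
from .geometry import (
    count_by_network_pair,
    default_roi_metadata,
    edge_distances_by_network_pair,
)
from .io import save_cohort, save_json, save_manifest
from .lme import PiecewiseLME, contrast_table
from .nbs import NetworkBasedStatistic, nbs_report
from .association import AugmentedModelSpec, association_test
from .posthoc import classify_individual_changes, effect_size_region

logger = logging.getLogger("neurolong")

__all__ = ["PipelineConfig", "run_pipeline", "simulate_dataset"]


@dataclass
class PipelineConfig:
    """Thresholds, sizes and seeds for one pipeline run."""

    output_dir: str | Path = "neurolong_out"
    seed: int = 0
    n_treatment: int = 31
    n_control: int = 29
    n_frames: int = 160
    spike_rate: float = 0.08
    fd_threshold: float = 0.5
    dvars_threshold: float = 1.8
    z_threshold: float = 1.96
    alpha: float = 0.05
    nbs_alpha: float = 0.05
    seed_alpha_base: float = 0.05
    n_bootstrap: int = 10_000
    fc_effect_r: float = 0.2
    region_effect_scale: float = 1.0
    cohort_params: CohortParams | None = None

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("bootstrap count must be >= 1")
        for name in ("fd_threshold", "dvars_threshold", "z_threshold",
                     "alpha", "nbs_alpha", "seed_alpha_base"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _nearest_psd(A: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((A + A.T) / 2.0)
    return (vecs * np.clip(vals, 1e-6, None)) @ vecs.T


def _base_correlation(roi_meta: pd.DataFrame) -> np.ndarray:
    """Block-structured latent correlation: tighter within a network."""
    nets = roi_meta["network"].to_numpy()
    same = nets[:, None] == nets[None, :]
    R = np.where(same, 0.3, 0.05)
    np.fill_diagonal(R, 1.0)
    return R


def _effect_edges(roi_meta: pd.DataFrame) -> list[tuple[int, int]]:
    """Between-network connections of the two hub ROIs carrying the effect."""
    nets = roi_meta["network"].tolist()
    hubs = [3, 10]  # 0-based rows of the two prefrontal hub regions
    edges = []
    for h in hubs:
        for j in range(len(nets)):
            if j != h and nets[j] != nets[h]:
                edges.append((min(h, j), max(h, j)))
    return sorted(set(edges))


def _region_truth(roi_meta: pd.DataFrame, scale: float) -> dict[str, tuple]:
    """Per-region generative fixed effects: two carry group-by-time effects.

    Region 4 (prefrontal hub) rises then returns (nonmonotonic); region 8
    (postcentral) rises monotonically; the rest follow the null.
    """
    base = (2.5, 0.0, 0.0, 0.0, 0.0, 0.0, -0.002, -0.002, -0.001)
    out = {}
    for k in range(len(roi_meta)):
        name = f"thickness_r{k + 1}"
        beta = list(base)
        if k == 3:  # rise then fall back
            beta[4], beta[5] = 0.012 * scale, -0.024 * scale
        elif k == 7:  # monotonic rise
            beta[4], beta[5] = 0.004 * scale, 0.0
        out[name] = tuple(beta)
    return out


def _design_columns(cohort: pd.DataFrame, t_break: float) -> np.ndarray:
    t = cohort["time"].to_numpy(float)
    S = cohort["group"].to_numpy(float)
    hinge = np.clip(t - t_break, 0.0, None)
    bdi_bar = cohort.groupby("subject")["bdi"].transform("mean").to_numpy(float)
    return np.column_stack(
        [
            np.ones_like(t), t, hinge, S, S * t, S * hinge,
            cohort["age"].to_numpy(float), bdi_bar,
            cohort["bdi"].to_numpy(float) - bdi_bar,
        ]
    )


def _add_outcomes(
    cohort: pd.DataFrame,
    betas: dict[str, tuple],
    t_break: float,
    sigma_b: float,
    sigma_e: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Extra outcome columns drawn from the piecewise model on the same design."""
    X = _design_columns(cohort, t_break)
    codes = pd.factorize(cohort["subject"])[0]
    out = cohort.copy()
    for name, beta in betas.items():
        b = sigma_b * rng.standard_normal(codes.max() + 1)
        out[name] = X @ np.asarray(beta) + b[codes] + sigma_e * rng.standard_normal(len(X))
    return out


def simulate_dataset(config: PipelineConfig) -> dict:
    """Cohort, per-region outcomes, behavioural score and scans, in memory."""
    roi_meta = default_roi_metadata()
    ss = np.random.SeedSequence(config.seed)
    s_cohort, s_regions, s_score, s_scans = (
        int(x.generate_state(1)[0] % (2**31)) for x in ss.spawn(4)
    )
    params = config.cohort_params or CohortParams(
        n_treatment=config.n_treatment, n_control=config.n_control, seed=s_cohort
    )
    cohort, truth = generate_cohort(params)
    t_break = params.t_break

    rng_regions = np.random.default_rng(s_regions)
    region_betas = _region_truth(roi_meta, config.region_effect_scale)
    cohort = _add_outcomes(
        cohort, region_betas, t_break, params.sigma_b, params.sigma_e, rng_regions
    )
    # behavioural score in scaled-score units: treatment gains ~1.7 points
    rng_score = np.random.default_rng(s_score)
    score_beta = (8.2, 0.0, 0.0, 0.0, 0.08, -0.08, 0.0, 0.0, 0.0)
    cohort = _add_outcomes(
        cohort, {"trail_switch": score_beta}, t_break, 1.8, 1.0, rng_score
    )

    base_R = _base_correlation(roi_meta)
    effect_edges = _effect_edges(roi_meta)
    scans = []
    rng_scan = np.random.default_rng(s_scans)
    for _, row in cohort.iterrows():
        R = base_R.copy()
        if row["group"] == 1 and config.fc_effect_r:
            bump = config.fc_effect_r * row["time"] / 21.0
            for i, j in effect_edges:
                R[i, j] += bump
                R[j, i] += bump
            R = _nearest_psd(R)
        scan = generate_scan(
            R,
            config.n_frames,
            SpikeParams(rate=config.spike_rate),
            seed=int(rng_scan.integers(2**31)),
            scan_id=f"{row['subject']}_tp{row['timepoint']}",
            subject_id=row["subject"],
            timepoint=int(row["timepoint"]),
        )
        scans.append(scan)
    truth["region_betas"] = region_betas
    truth["score_beta"] = {"trail_switch": score_beta}
    truth["fc_effect_edges"] = effect_edges
    return {
        "cohort": cohort,
        "scans": scans,
        "roi_meta": roi_meta,
        "params": params,
        "truth": truth,
        "t_break": t_break,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic dataset; write artifacts; return results."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = simulate_dataset(config)
    cohort, scans, roi_meta = data["cohort"], data["scans"], data["roi_meta"]
    save_cohort(cohort, out / "cohort.tsv")
    save_manifest(dataclasses.asdict(config.cohort_params or CohortParams()),
                  data["truth"], out / "manifest.json")

    # --- connectivity QA ---------------------------------------------------
    qa_log = []
    kept_scans, kept_series, fd_after = [], [], []
    for scan in scans:
        try:
            mask = scrub_frames(
                scan, config.fd_threshold, config.dvars_threshold
            )
        except QAError as exc:
            qa_log.append({"scan": scan.scan_id, "rule": "all_frames_scrubbed",
                           "detail": str(exc)})
            continue
        if not mask.passes_floor:
            qa_log.append({
                "scan": scan.scan_id, "rule": "below_4min_floor",
                "detail": f"{mask.seconds_retained:.0f}s retained",
            })
            continue
        kept_scans.append(scan)
        kept_series.append(apply_mask(scan, mask))
        fd_after.append(float(scan.motion_fd[mask.keep].mean()))
    trimmed = trim_to_common_length(kept_series)
    conns = [
        compute_connectivity(
            ts, scan_id=s.scan_id, subject_id=s.subject_id,
            timepoint=s.timepoint, fd_mean_after=fd,
        )
        for ts, s, fd in zip(trimmed, kept_scans, fd_after)
    ]
    std_stack, edge_table = standardize_edges(conns)
    edge_table.to_csv(out / "edges.tsv", sep="\t", index=False)

    # --- thickness models --------------------------------------------------
    region_cols = [c for c in cohort.columns if c.startswith("thickness_r")]
    fits, tables = {}, []
    for region in region_cols:
        est = PiecewiseLME(outcome=region).fit(cohort)
        fits[region] = est
        tab = contrast_table(est)
        tab.insert(0, "region", region)
        tables.append(tab)
    thickness_table = pd.concat(tables, ignore_index=True)
    thickness_table.to_csv(out / "thickness_contrasts.tsv", sep="\t", index=False)

    # --- network statistics ------------------------------------------------
    visit_key = cohort.set_index(["subject", "timepoint"])
    design = pd.DataFrame(
        {
            "subject": [s.subject_id for s in kept_scans],
            "timepoint": [s.timepoint for s in kept_scans],
            "fd": fd_after,
        }
    )
    for col in ("group", "time", "age", "bdi"):
        design[col] = [
            visit_key.loc[(s.subject_id, s.timepoint), col] for s in kept_scans
        ]
    # persist the post-scrub FD summary with the visit table so the network
    # stage can restart from files alone
    cohort = cohort.merge(
        design[["subject", "timepoint", "fd"]], on=["subject", "timepoint"],
        how="left",
    )
    save_cohort(cohort, out / "cohort.tsv")
    nbs = NetworkBasedStatistic(
        contrast_label="monotonic",
        scope="between",
        threshold=config.z_threshold,
        n_bootstrap=config.n_bootstrap,
        random_state=config.seed + 1,
    ).fit(std_stack, design)
    report = nbs_report(nbs.result_, roi_meta, alpha=config.nbs_alpha)
    report.to_csv(out / "nbs_components.tsv", sep="\t", index=False)
    save_json(nbs.result_.to_dict(), out / "nbs_result.json")

    # --- post hoc ----------------------------------------------------------
    posthoc_frames = []
    effect_sizes = {}
    for region in region_cols:
        flags = classify_individual_changes(cohort, region, reference_group=0)
        flags.insert(0, "region_name", region)
        posthoc_frames.append(flags)
        abs_c, pct = effect_size_region(
            cohort, region, group=1, pattern="nonmonotonic", fit=fits[region]
        )
        abs_m, pct_m = effect_size_region(
            cohort, region, group=1, pattern="monotonic", fit=fits[region]
        )
        effect_sizes[region] = {
            "nonmonotonic_mm": abs_c, "nonmonotonic_pct": pct,
            "monotonic_mm": abs_m, "monotonic_pct": pct_m,
        }
    pd.concat(posthoc_frames, ignore_index=True).to_csv(
        out / "posthoc_flags.tsv", sep="\t", index=False
    )
    save_json(effect_sizes, out / "effect_sizes.json")

    # --- demographic battery ----------------------------------------------
    demo = {
        "gender_fisher_p": fisher_exact(reference.GENDER_TABLE),
        "civilian_veteran_fisher_p": fisher_exact(reference.CIVILIAN_VETERAN_TABLE),
        "severity": dataclasses.asdict(
            likelihood_ratio_chisq(reference.SEVERITY_TABLE)
        ),
        "injury_cause": dataclasses.asdict(
            likelihood_ratio_chisq(reference.INJURY_CAUSE_TABLE)
        ),
        "current_iq_t_p": two_sample_t_from_summary(*reference.CURRENT_IQ)[2],
        "premorbid_iq_t_p": two_sample_t_from_summary(*reference.PREMORBID_IQ)[2],
    }
    save_json(demo, out / "demographics.json")
    _, score_table = behavior_lme(cohort, "trail_switch", covariate_set="bdi_only")
    score_table.to_csv(out / "behavior_contrasts.tsv", sep="\t", index=False)

    # --- brain-behaviour association ---------------------------------------
    assoc_spec = AugmentedModelSpec(
        score="trail_switch", residualization_set=("age", "bdi")
    )
    assoc = {}
    for region, mode in (("thickness_r4", "nonmonotonic"), ("thickness_r8", "monotonic")):
        res = association_test(cohort, region, assoc_spec, mode=mode)
        assoc[region] = {"mode": mode, "estimate": res.estimate,
                         "se": res.se, "z": res.z, "p": res.p}
    save_json(assoc, out / "associations.json")

    # --- geometry of significant connectivity ------------------------------
    sig_edges = sorted(
        {e for c, p in zip(nbs.components_, nbs.p_values_) if p < config.nbs_alpha
         for e in c}
    )
    indexed = [(i + 1, j + 1) for i, j in sig_edges]  # metadata is 1-based
    geometry = {
        "network_pair_counts": count_by_network_pair(indexed, roi_meta),
        "distances": edge_distances_by_network_pair(indexed, roi_meta).to_dict(
            orient="records"
        ),
    }
    save_json(geometry, out / "network_geometry.json")
    save_json(qa_log, out / "qa_report.json")
    for entry in qa_log:
        logger.info("QA exclusion: %s (%s)", entry["scan"], entry["rule"])

    return {
        "cohort": cohort,
        "edge_table": edge_table,
        "thickness_table": thickness_table,
        "nbs": nbs,
        "nbs_report": report,
        "effect_sizes": effect_sizes,
        "demographics": demo,
        "behavior_table": score_table,
        "associations": assoc,
        "geometry": geometry,
        "qa_log": qa_log,
        "truth": data["truth"],
    }
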