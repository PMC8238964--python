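"""End-to-end orchestration: manifest-driven subject and cohort runs.

A manifest CSV (columns: subject_id, age, sbp, site, state, path) pairs
each subject's per-site baseline / compressed / hyperemia en-face
images. Per subject-site the pipeline destripes, segments, measures the
metric quadruple per state and forms the RCC from the baseline /
hyperemia pair; compressed images are quality-control only (their
measured VD must be near zero). Cohort runs aggregate per-subject RCC
(sites averaged), produce group summaries, Welch comparisons and
regressions of RCC on age and systolic blood pressure, and record full
provenance (config, seeds, software version) for reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .images import EnFaceImage, read_enface_tiff, write_enface_tiff
from .metrics import RCCResult, VesselMetrics, compute_rcc, image_metrics
from .preprocess import remove_stripes
from .segmentation import segment_vessels, skeletonize
from .stats import compare_groups, regress, summarize
from .synthetic import (
    ArtifactParams,
    BranchingParams,
    generate_network,
    render_enface,
    add_artifacts,
)

MANIFEST_COLUMNS = ("subject_id", "age", "sbp", "site", "state", "path")


@dataclass
class RunConfig:
    """All knobs of an end-to-end run; serialized into provenance."""

    pixel_pitch_um: float = 6.5
    depth_range_um: tuple[float, float] = (40.0, 440.0)
    # destriping
    destripe_levels: int = 5
    destripe_wavelet: str = "db4"
    destripe_sigma: float = 2.4
    stripe_axis: str = "fast"
    # segmentation
    scales_um: Optional[tuple[float, ...]] = None
    low_frac: float = 0.35
    high_frac: float = 0.65
    gate_frac: float = 0.35
    smooth_sigma: float = 1.0
    min_object_px: int = 25
    prune_px: int = 8
    # metrics / statistics
    length_estimator: str = "calibrated"
    aggregation: str = "mean_over_sites"
    equal_var: bool = False
    compressed_vd_qc_pct: float = 2.0
    # bookkeeping
    seed: int = 0
    output_dir: str = "results"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["depth_range_um"] = list(self.depth_range_um)
        if self.scales_um is not None:
            d["scales_um"] = list(self.scales_um)
        return d


@dataclass
class SubjectResult:
    subject_id: str
    site: str
    rcc: RCCResult
    metrics: dict[str, VesselMetrics]  # state -> metrics
    qc_warnings: list[str] = field(default_factory=list)


class ManifestError(ValueError):
    """Malformed manifest content, reported with the offending row."""


def analyze_image(image: EnFaceImage, config: RunConfig) -> VesselMetrics:
    """Destripe, segment, skeletonize and measure one en-face image."""
    clean = remove_stripes(
        image,
        levels=config.destripe_levels,
        wavelet=config.destripe_wavelet,
        damping_sigma=config.destripe_sigma,
        stripe_axis=config.stripe_axis,
    )
    mask = segment_vessels(
        clean,
        scales_um=config.scales_um,
        low_frac=config.low_frac,
        high_frac=config.high_frac,
        min_object_px=config.min_object_px,
        gate_frac=config.gate_frac,
        smooth_sigma=config.smooth_sigma,
    )
    skel = skeletonize(mask, prune_px=config.prune_px)
    return image_metrics(mask, skel, estimator=config.length_estimator)


def run_subject(
    images: dict[str, EnFaceImage],
    config: RunConfig,
    subject_id: str = "",
    site: str = "",
) -> SubjectResult:
    """Analyze one subject-site state set and form the RCC.

    ``images`` maps state labels to en-face images; baseline and
    hyperemia are required, compressed is optional and used only for the
    flow-suppression QC check (measured VD above the configured bound
    raises a warning, not an error).
    """
    for required in ("baseline", "hyperemia"):
        if required not in images:
            raise ManifestError(
                f"subject {subject_id or '?'} site {site or '?'}: "
                f"missing state {required!r}"
            )
    metrics = {state: analyze_image(img, config) for state, img in images.items()}
    qc: list[str] = []
    if "compressed" in metrics and metrics["compressed"].vd > config.compressed_vd_qc_pct:
        msg = (
            f"subject {subject_id} site {site}: compressed-state VD "
            f"{metrics['compressed'].vd:.2f}% exceeds the "
            f"{config.compressed_vd_qc_pct}% flow-suppression QC bound"
        )
        qc.append(msg)
        warnings.warn(msg, stacklevel=2)
    rcc = compute_rcc(metrics["baseline"], metrics["hyperemia"])
    return SubjectResult(subject_id, site, rcc, metrics, qc)


# ---------------------------------------------------------------------------
# manifest handling


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a manifest CSV."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest is missing columns: {missing}")
    base = Path(path).parent
    for idx, row in df.iterrows():
        if row["state"] not in ("baseline", "compressed", "hyperemia"):
            raise ManifestError(f"manifest row {idx + 1}: unknown state {row['state']!r}")
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise ManifestError(f"manifest row {idx + 1}: image not found: {p}")
        df.loc[idx, "path"] = str(p)
    return df


def _age_group(age: float) -> Optional[str]:
    if 18 <= age <= 30:
        return "young"
    if age >= 65:
        return "old"
    return None


def _bp_group(sbp: float) -> str:
    return "ge130" if sbp >= 130 else "lt130"


# ---------------------------------------------------------------------------
# cohort run


def run_cohort(manifest_path: str | Path, config: RunConfig) -> dict[str, Path]:
    """Run every subject in a manifest and write the cohort tables.

    Outputs (all under ``config.output_dir``): metrics.csv (one row per
    image), rcc.csv (per subject-site and the per-subject mean),
    summary.csv (group means +- SD per metric), comparisons.csv (Welch
    tests young/old and lt130/ge130 per metric), regressions.csv (RCC on
    age and on SBP), provenance.json. Returns the written paths.
    """
    df = load_manifest(manifest_path)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    metric_rows = []
    rcc_rows = []
    for (subject_id, site), grp in sorted(df.groupby(["subject_id", "site"])):
        images = {}
        for _, row in grp.iterrows():
            images[row["state"]] = read_enface_tiff(
                row["path"], pixel_pitch_um=config.pixel_pitch_um, state=row["state"], site=site
            )
        result = run_subject(images, config, subject_id=subject_id, site=site)
        age = float(grp["age"].iloc[0])
        sbp = float(grp["sbp"].iloc[0])
        for state in sorted(result.metrics):
            m = result.metrics[state]
            metric_rows.append(
                {
                    "subject_id": subject_id,
                    "site": site,
                    "state": state,
                    "vd": m.vd,
                    "lvn": m.lvn,
                    "nbp": m.nbp,
                    "diameter_um": m.diameter_um,
                    "field_area_mm2": m.field_area_mm2,
                }
            )
        rcc_rows.append(
            {
                "subject_id": subject_id,
                "site": site,
                "age": age,
                "sbp": sbp,
                "rcc": result.rcc.rcc,
            }
        )

    metrics_df = pd.DataFrame(metric_rows).sort_values(["subject_id", "site", "state"])
    rcc_df = pd.DataFrame(rcc_rows).sort_values(["subject_id", "site"])
    # per-subject aggregation: average RCC over sites
    subject_df = (
        rcc_df.groupby("subject_id", as_index=False)
        .agg(age=("age", "first"), sbp=("sbp", "first"), rcc=("rcc", "mean"))
        .sort_values("subject_id")
    )
    subject_df["group_age"] = [_age_group(a) for a in subject_df["age"]]
    subject_df["group_bp"] = [_bp_group(s) for s in subject_df["sbp"]]

    summary_rows, comparison_rows = _cohort_tables(metrics_df, subject_df, config)

    regression_rows = []
    for predictor in ("age", "sbp"):
        x = subject_df[predictor].to_numpy()
        y = subject_df["rcc"].to_numpy()
        if len(x) >= 3 and np.ptp(x) > 0:
            res = regress(x, y)
            regression_rows.append(
                {
                    "response": "rcc",
                    "predictor": predictor,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "r_squared": res.r_squared,
                    "p_value": res.p_value,
                    "n": res.n,
                }
            )

    paths = {}

    def _write(name: str, frame: pd.DataFrame) -> None:
        p = out_dir / name
        frame.to_csv(p, index=False, float_format="%.6f")
        paths[name] = p

    _write("metrics.csv", metrics_df)
    _write("rcc.csv", rcc_df)
    _write("subjects.csv", subject_df)
    _write("summary.csv", pd.DataFrame(summary_rows))
    _write("comparisons.csv", pd.DataFrame(comparison_rows))
    _write("regressions.csv", pd.DataFrame(regression_rows))

    provenance = {
        "software": {"name": "rhocta", "version": __version__},
        "config": config.to_dict(),
        "manifest": str(manifest_path),
        "n_subjects": int(subject_df.shape[0]),
        "n_images": int(metrics_df.shape[0]),
        "multiple_testing_correction": "none",
    }
    prov_path = out_dir / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=1, sort_keys=True))
    paths["provenance.json"] = prov_path
    return paths


def _cohort_tables(
    metrics_df: pd.DataFrame, subject_df: pd.DataFrame, config: RunConfig
) -> tuple[list[dict], list[dict]]:
    """Group summary rows and pairwise comparison rows."""
    # per-subject metric means by state (sites averaged), joined to groups
    per_subject = (
        metrics_df.groupby(["subject_id", "state"], as_index=False)[
            ["vd", "lvn", "nbp", "diameter_um"]
        ].mean()
    ).merge(subject_df[["subject_id", "group_age", "group_bp", "rcc"]], on="subject_id")

    state_method = {"baseline": "octa", "hyperemia": "rh_octa"}
    summary_rows: list[dict] = []
    comparison_rows: list[dict] = []
    groupings = (("group_age", ("young", "old")), ("group_bp", ("lt130", "ge130")))
    for state, method in state_method.items():
        sub = per_subject[per_subject["state"] == state]
        for metric in ("vd", "lvn", "nbp", "diameter_um"):
            for col, names in groupings:
                groups = {
                    name: sub.loc[sub[col] == name, metric].tolist()
                    for name in names
                    if (sub[col] == name).any()
                }
                for s in summarize(groups, metric=metric):
                    summary_rows.append(
                        {
                            "method": method,
                            "grouping": col,
                            "group": s.group,
                            "metric": s.metric,
                            "mean": s.mean,
                            "sd": s.sd,
                            "n": s.n,
                            "degenerate": s.degenerate,
                        }
                    )
                if all(len(groups.get(n, [])) >= 2 for n in names):
                    t, p = compare_groups(
                        groups[names[0]], groups[names[1]], equal_var=config.equal_var
                    )
                    comparison_rows.append(
                        {
                            "method": method,
                            "metric": metric,
                            "group_a": names[0],
                            "group_b": names[1],
                            "t": t,
                            "p": p,
                        }
                    )
    # RCC rows (method-independent)
    for col, names in groupings:
        groups = {
            name: subject_df.loc[subject_df[col] == name, "rcc"].tolist()
            for name in names
            if (subject_df[col] == name).any()
        }
        for s in summarize(groups, metric="rcc"):
            summary_rows.append(
                {
                    "method": "rcc",
                    "grouping": col,
                    "group": s.group,
                    "metric": "rcc",
                    "mean": s.mean,
                    "sd": s.sd,
                    "n": s.n,
                    "degenerate": s.degenerate,
                }
            )
        if all(len(groups.get(n, [])) >= 2 for n in names):
            t, p = compare_groups(groups[names[0]], groups[names[1]], equal_var=config.equal_var)
            comparison_rows.append(
                {
                    "method": "rcc",
                    "metric": "rcc",
                    "group_a": names[0],
                    "group_b": names[1],
                    "t": t,
                    "p": p,
                }
            )
    return summary_rows, comparison_rows


# ---------------------------------------------------------------------------
# synthetic cohorts


def synthesize_cohort(
    out_dir: str | Path,
    n_young: int = 4,
    n_old: int = 4,
    seed: int = 0,
    field_size_mm: float = 1.5015,
    target_density: float = 0.25,
    young_unperfused_frac: float = 0.6,
    old_unperfused_frac: float = 0.4,
    artifacts: bool = True,
    sites: Sequence[str] = ("inner",),
    write_compressed: bool = True,
) -> Path:
    """Write a synthetic cohort (images + manifest) and return the manifest path.

    Young subjects receive the default unperfused-terminal fraction, old
    subjects a lower one: fewer unperfused capillaries at baseline means
    less recruitable reserve and therefore a generator-set lower RCC,
    the direction the published cohorts show. Ages and SBP are drawn
    from group-typical ranges (SBP correlates with age group). The truth
    RCC per subject-site is recorded in truth.csv alongside the images.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    subjects = [("Y", i, young_unperfused_frac) for i in range(n_young)] + [
        ("O", i, old_unperfused_frac) for i in range(n_old)
    ]
    for tag, i, unperfused in subjects:
        subject_id = f"{tag}{i:02d}"
        if tag == "Y":
            age = float(rng.integers(18, 31))
            sbp = float(rng.integers(105, 132))
        else:
            age = float(rng.integers(65, 86))
            sbp = float(rng.integers(118, 160))
        for site in sites:
            net_seed = int(rng.integers(0, 2**31 - 1))
            params = BranchingParams(unperfused_terminal_frac=unperfused)
            network = generate_network(
                field_size_mm=field_size_mm,
                target_density=target_density,
                branching_params=params,
                seed=net_seed,
            )
            truth = {}
            for state in ("baseline", "compressed", "hyperemia"):
                if state == "compressed" and not write_compressed:
                    continue
                image, tm = render_enface(network, state)
                if artifacts:
                    art_seed = int(rng.integers(0, 2**31 - 1))
                    image = add_artifacts(image, ArtifactParams(seed=art_seed))
                name = f"{subject_id}_{site}_{state}.tif"
                write_enface_tiff(image, out / name)
                rows.append(
                    {
                        "subject_id": subject_id,
                        "age": age,
                        "sbp": sbp,
                        "site": site,
                        "state": state,
                        "path": name,
                    }
                )
                truth[state] = tm
            rcc_truth = (
                (truth["hyperemia"].area_fraction / truth["baseline"].area_fraction)
                * (
                    truth["hyperemia"].centerline_length_per_area
                    / truth["baseline"].centerline_length_per_area
                )
                * (truth["hyperemia"].branch_count / truth["baseline"].branch_count)
                - 1.0
            )
            truth_rows.append(
                {
                    "subject_id": subject_id,
                    "site": site,
                    "net_seed": net_seed,
                    "rcc_truth": rcc_truth,
                }
            )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False, float_format="%.6f")
    return manifest
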