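"""End-to-end experiment drivers.

Each driver takes a :class:`RunConfig` and a sample sheet (CSV or DataFrame),
runs the corresponding measurement chain deterministically, and writes CSV
outputs whose header comments embed the package version and a hash of the
configuration, so results are auditable and byte-reproducible.

Sample sheet columns: ``sample_id, genotype, role, stage, channel,
image_path, mask_path`` where ``role`` is one of ``test``,
``negative_control``, ``positive_control``, ``no_primary``. The expression
filter uses the ``negative_control`` rows when present, otherwise the
``no_primary`` rows (the convention for backgrounds that cannot provide a
genetic negative control).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, asdict, field
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .colocalization import coloc_threshold, pearson_colocalization, select_coloc_pixels
from .enrichment import ap_profile, expression_filter, zscore_within_mask
from .exceptions import ConsistencyError, GermquantError, ParameterError
from .io import TissueMask, compute_mask, read_mask, read_stack, sum_projection
from .radial import radial_slope_workflow
from .stats import (
    DEFAULT_CATEGORIES,
    PhenotypeCounts,
    compare_groups,
    jensen_shannon_divergence,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "load_sample_sheet",
    "run_enrichment",
    "run_coloc",
    "run_radial",
    "run_phenotypes",
]

ROLES = ("test", "negative_control", "positive_control", "no_primary")


@dataclass(frozen=True)
class RunConfig:
    """Analysis constants; defaults are the conventional ones for this
    pipeline (posterior 15% cap, 3-SD expression filter, 2-SD coloc gate,
    20 erosion iterations, 100,000 bootstrap resamples)."""

    posterior_fraction: float = 0.15
    filter_k: float = 3.0
    coloc_k_sd: float = 2.0
    n_bins: int = 100
    n_iter: int = 20
    B: int = 100_000
    alpha: float = 0.05
    seed: int = 0
    negative_label: str = "negative_control"
    positive_label: str = "positive_control"
    no_primary_label: str = "no_primary"
    projection_axis: str = "x"
    connectivity: int = 4
    min_points: int = 5
    min_coloc_pixels: int = 10
    voxel_size: tuple = (2.0, 0.65, 0.65)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ParameterError(f"unknown config keys: {sorted(bad)}")
        if "voxel_size" in raw:
            raw["voxel_size"] = tuple(raw["voxel_size"])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["voxel_size"] = list(d["voxel_size"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def digest(self) -> str:
        d = asdict(self)
        d["voxel_size"] = list(d["voxel_size"])
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


def load_sample_sheet(sheet: Union[str, pd.DataFrame]) -> pd.DataFrame:
    """Load and validate a sample sheet."""
    df = pd.read_csv(sheet) if isinstance(sheet, str) else sheet.copy()
    required = {"sample_id", "genotype", "role", "channel", "image_path"}
    missing = required - set(df.columns)
    if missing:
        raise ConsistencyError(f"sample sheet missing columns: {sorted(missing)}")
    if "stage" not in df.columns:
        df["stage"] = "embryo"
    if "mask_path" not in df.columns:
        df["mask_path"] = None
    bad_roles = set(df["role"]) - set(ROLES)
    if bad_roles:
        raise ConsistencyError(f"unknown roles in sheet: {sorted(bad_roles)}")
    dup = df.duplicated(subset=["sample_id", "channel"])
    if dup.any():
        raise ConsistencyError(
            f"duplicate (sample_id, channel) rows: {df.loc[dup, 'sample_id'].tolist()}"
        )
    for p in df["image_path"]:
        if not os.path.exists(p):
            raise IOError(f"image file missing: {p}")
    return df


def _write_csv(df: pd.DataFrame, path: str, config: RunConfig) -> None:
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# germquant {__version__}\n# config_hash: {config.digest()}\n")
        df.to_csv(fh, index=False)


def _load_mask(row, projection) -> TissueMask:
    if row.mask_path and isinstance(row.mask_path, str) and os.path.exists(row.mask_path):
        return read_mask(row.mask_path)
    return compute_mask(projection)


def _sample_measurements(config: RunConfig, sheet: pd.DataFrame) -> pd.DataFrame:
    """Per (sample, channel) enrichment metrics."""
    rows = []
    for row in sheet.itertuples(index=False):
        stack = read_stack(row.image_path, voxel_size=config.voxel_size, channel=row.channel)
        proj = sum_projection(stack)
        mask = _load_mask(row, proj)
        zmap = zscore_within_mask(proj, mask)
        profile = ap_profile(
            zmap, n_bins=config.n_bins, posterior_fraction=config.posterior_fraction
        )
        rows.append(
            {
                "sample_id": row.sample_id,
                "genotype": row.genotype,
                "role": row.role,
                "stage": row.stage,
                "channel": row.channel,
                "n_masked_pixels": int(mask.footprint_2d().sum()),
                "mean_posterior_z": profile.mean_posterior_z,
                "integrated_posterior": profile.integrated_posterior,
            }
        )
    return pd.DataFrame(rows)


def run_enrichment(
    config: RunConfig,
    sheet: Union[str, pd.DataFrame],
    outdir: str,
    ha_channel: str = "HA",
    apply_filter: bool = True,
) -> Dict[str, pd.DataFrame]:
    """Enrichment experiment: projections -> z-scores -> AP profiles ->
    expression filter -> bootstrap group comparisons.

    The filter is computed on the HA channel's mean posterior enrichment
    against the negative-control (or no-primary) distribution; only passing
    samples contribute to group statistics, but all samples are written to
    the per-sample CSV with their filter decision.
    """
    df = load_sample_sheet(sheet)
    per_sample = _sample_measurements(config, df)

    filtered = per_sample.copy()
    filtered["filter_passed"] = True
    if apply_filter:
        ha = per_sample[per_sample["channel"] == ha_channel]
        if ha.empty:
            raise ConsistencyError(
                f"filtering requested but no {ha_channel!r} channel rows present"
            )
        ctrl_role = config.negative_label
        controls = ha[ha["role"] == ctrl_role]
        if controls.empty:
            ctrl_role = config.no_primary_label
            controls = ha[ha["role"] == ctrl_role]
        if controls.empty:
            raise ConsistencyError(
                "filter needs negative_control or no_primary samples on the HA channel"
            )
        result = expression_filter(
            ha["mean_posterior_z"].to_numpy(),
            controls["mean_posterior_z"].to_numpy(),
            k=config.filter_k,
        )
        decisions = dict(zip(ha["sample_id"], result.passed))
        filtered["filter_passed"] = filtered["sample_id"].map(decisions).fillna(False)
        logger.info(
            "expression filter (vs %s): threshold=%.4g, %d/%d samples pass",
            ctrl_role, result.threshold, int(result.passed.sum()), len(result.passed),
        )

    comparisons = []
    eligible = filtered[
        (filtered["filter_passed"]) | (~filtered["role"].eq("test"))
    ]
    readout_channels = set(eligible["channel"]) - ({ha_channel} if apply_filter else set())
    if not readout_channels:
        readout_channels = set(eligible["channel"])  # HA itself is the readout
    for (stage, channel), sub in eligible.groupby(["stage", "channel"]):
        if channel not in readout_channels:
            continue
        tab = sub.rename(columns={"integrated_posterior": "value"})
        tab = tab[tab["role"].isin(["test", "negative_control", "positive_control"])]
        test_genotypes = tab.loc[tab["role"] == "test", "genotype"].unique()
        if len(test_genotypes) == 0:
            logger.info("stage=%s channel=%s: no test samples pass the filter", stage, channel)
            continue
        pos = tab.loc[tab["role"] == "positive_control", "genotype"].unique()
        neg = tab.loc[tab["role"] == "negative_control", "genotype"].unique()
        controls = list(pos[:1]) + list(neg[:1])
        if not controls:
            logger.info("stage=%s channel=%s: no control group, comparison skipped", stage, channel)
            continue
        comp = compare_groups(
            tab[tab["genotype"].isin(list(test_genotypes) + controls)],
            positive_label=controls[0],
            negative_label=controls[1] if len(controls) > 1 else None,
            B=config.B,
            seed=config.seed,
            alpha=config.alpha,
        )
        comp.insert(0, "stage", stage)
        comp.insert(1, "channel", channel)
        comparisons.append(comp)
    comparison = (
        pd.concat(comparisons, ignore_index=True) if comparisons else pd.DataFrame()
    )
    if comparison.empty:
        logger.info("no group comparisons emitted (no eligible test samples)")

    _write_csv(filtered, os.path.join(outdir, "enrichment_per_sample.csv"), config)
    _write_csv(comparison, os.path.join(outdir, "enrichment_comparisons.csv"), config)
    return {"per_sample": filtered, "comparisons": comparison}


def run_coloc(
    config: RunConfig,
    sheet: Union[str, pd.DataFrame],
    outdir: str,
    ha_channel: str = "HA",
) -> pd.DataFrame:
    """Colocalization experiment: Pearson r between the HA channel and every
    other channel of each sample, over gated posterior pixels."""
    df = load_sample_sheet(sheet)
    rows = []
    for sid, sub in df.groupby("sample_id"):
        ha_rows = sub[sub["channel"] == ha_channel]
        if ha_rows.empty:
            raise ConsistencyError(f"sample {sid}: no {ha_channel!r} channel")
        ha_row = next(ha_rows.itertuples(index=False))
        ha_stack = read_stack(ha_row.image_path, config.voxel_size, channel=ha_channel)
        ha_proj = sum_projection(ha_stack)
        mask = _load_mask(ha_row, ha_proj)
        pixels = select_coloc_pixels(
            ha_proj, mask,
            posterior_fraction=config.posterior_fraction,
            k_sd=config.coloc_k_sd,
        )
        thr = coloc_threshold(ha_proj, mask, k_sd=config.coloc_k_sd)
        for row in sub[sub["channel"] != ha_channel].itertuples(index=False):
            other = read_stack(row.image_path, config.voxel_size, channel=row.channel)
            res = pearson_colocalization(
                ha_proj, sum_projection(other), pixels,
                min_pixels=config.min_coloc_pixels,
                ha_threshold=thr,
                posterior_fraction=config.posterior_fraction,
                k_sd=config.coloc_k_sd,
            )
            rows.append(
                {
                    "sample_id": sid,
                    "genotype": row.genotype,
                    "role": row.role,
                    "target_channel": row.channel,
                    "n_pixels": res.n_pixels,
                    "r": res.r,
                    "ha_threshold": res.ha_threshold,
                }
            )
    out = pd.DataFrame(rows)
    _write_csv(out, os.path.join(outdir, "colocalization.csv"), config)
    return out


def run_radial(
    config: RunConfig,
    sheet: Union[str, pd.DataFrame],
    outdir: str,
) -> Dict[str, pd.DataFrame]:
    """Radial-distribution experiment: per-sample erosion profile slope plus
    pairwise bootstrap comparisons of slope distributions by genotype."""
    df = load_sample_sheet(sheet)
    rows = []
    for row in df.itertuples(index=False):
        stack = read_stack(row.image_path, config.voxel_size, channel=row.channel)
        if row.mask_path and isinstance(row.mask_path, str) and os.path.exists(row.mask_path):
            mask = read_mask(row.mask_path)
        else:
            mask = compute_mask(sum_projection(stack))
        profile = radial_slope_workflow(
            stack, mask,
            n_iter=config.n_iter,
            min_points=config.min_points,
            connectivity=config.connectivity,
            projection_axis=config.projection_axis,
        )
        rec = {
            "sample_id": row.sample_id,
            "genotype": row.genotype,
            "role": row.role,
            "n_valid": profile.n_valid,
            "slope": profile.slope,
            "intercept": profile.intercept,
        }
        for i in range(config.n_iter + 1):
            rec[f"mean_{i}"] = profile.means[i] if i < profile.n_valid else np.nan
        rows.append(rec)
    per_sample = pd.DataFrame(rows)

    comparisons = pd.DataFrame()
    genotypes = sorted(per_sample["genotype"].unique())
    if len(genotypes) >= 2 and (per_sample.groupby("genotype").size() >= 2).all():
        from .stats import bootstrap_diff_means
        from .stats import _derive_seed
        comps = []
        i = 0
        for a_idx in range(len(genotypes)):
            for b_idx in range(a_idx + 1, len(genotypes)):
                a, b = genotypes[a_idx], genotypes[b_idx]
                test = bootstrap_diff_means(
                    per_sample.loc[per_sample["genotype"] == a, "slope"].to_numpy(),
                    per_sample.loc[per_sample["genotype"] == b, "slope"].to_numpy(),
                    B=config.B,
                    seed=_derive_seed(config.seed, i),
                )
                comps.append(
                    {
                        "genotype_a": a,
                        "genotype_b": b,
                        "observed_diff": test.observed_diff,
                        "p_value": test.p_value,
                        "significant": test.p_value < config.alpha,
                    }
                )
                i += 1
        comparisons = pd.DataFrame(comps)
    else:
        logger.info("fewer than 2 genotypes with >= 2 samples: comparison skipped")

    _write_csv(per_sample, os.path.join(outdir, "radial_per_sample.csv"), config)
    _write_csv(comparisons, os.path.join(outdir, "radial_comparisons.csv"), config)
    return {"per_sample": per_sample, "comparisons": comparisons}


def run_phenotypes(
    config: RunConfig,
    counts: Union[str, pd.DataFrame],
    outdir: Optional[str] = None,
) -> pd.DataFrame:
    """Score each genotype's phenotype distribution against both controls.

    ``counts`` is a CSV/DataFrame with columns: genotype, role, then one
    column per category. Emits one row per non-control genotype with
    ``jsd_vs_negative`` and ``jsd_vs_positive``.
    """
    df = pd.read_csv(counts, comment="#") if isinstance(counts, str) else counts.copy()
    cat_cols = [c for c in df.columns if c not in ("genotype", "role")]
    if not cat_cols:
        raise ConsistencyError("phenotype table has no category columns")

    def table_for(sub: pd.DataFrame) -> PhenotypeCounts:
        return PhenotypeCounts(
            counts=tuple(int(v) for v in sub[cat_cols].iloc[0]),
            categories=tuple(cat_cols),
        )

    neg = df[df["role"] == "negative_control"]
    pos = df[df["role"] == "positive_control"]
    if neg.empty or pos.empty:
        raise ConsistencyError("phenotype table needs negative_control and positive_control rows")
    neg_t, pos_t = table_for(neg), table_for(pos)
    rows = []
    for _, r in df[df["role"] == "test"].iterrows():
        t = PhenotypeCounts(
            counts=tuple(int(v) for v in r[cat_cols]), categories=tuple(cat_cols)
        )
        rows.append(
            {
                "genotype": r["genotype"],
                "jsd_vs_negative": jensen_shannon_divergence(t, neg_t).jsd,
                "jsd_vs_positive": jensen_shannon_divergence(t, pos_t).jsd,
            }
        )
    out = pd.DataFrame(rows, columns=["genotype", "jsd_vs_negative", "jsd_vs_positive"])
    if outdir is not None:
        _write_csv(out, os.path.join(outdir, "phenotype_jsd.csv"), config)
    return out
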