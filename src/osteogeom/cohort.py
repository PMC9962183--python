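"""Cohort-level aggregation and healthy-vs-osteoporotic comparisons.

Per-section properties are flattened into a long-format table; comparisons
are two-sample tests (Welch's t by default, Mann-Whitney optional) per
property per level, summarized as group means, ratio of means (in percent,
osteoporotic over healthy), and a significance flag.  Thickness matrices
(sections x rays) back per-specimen maps and anatomical-sector contrasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .csg import COMPARISON_PROPERTIES, SectionProperties
from .errors import ValidationError
from .sectioning import CrossSection, SamplingConfig, radial_thickness

__all__ = [
    "GroupComparison",
    "ThicknessMap",
    "build_cohort_table",
    "group_compare",
    "compare_all",
    "thickness_map",
    "regional_contrast",
    "render_heatmap",
    "summarize_run",
    "HEADLINE_LEVELS",
    "SECTOR_NAMES",
    "assign_sectors",
]

#: Levels at which the headline summary is reported (fractions of BL).
HEADLINE_LEVELS = (0.80, 0.60, 0.40, 0.20)

#: Anatomical quadrants of ray angles (left-femur convention, +x lateral,
#: +y anterior): each sector spans +/-45 degrees around its axis.
SECTOR_NAMES = ("lateral", "anterior", "medial", "posterior")

TESTS = ("welch", "mann_whitney")


@dataclass(frozen=True)
class GroupComparison:
    property_name: str
    level_fraction: float
    mean_healthy: float
    mean_osteo: float
    ratio_percent: float
    test_name: str
    statistic: float
    p_value: float
    significant: bool
    n_healthy: int
    n_osteo: int


@dataclass(frozen=True)
class ThicknessMap:
    """Radial thickness per (section, ray) for one specimen."""

    specimen_id: str
    group: str
    matrix: np.ndarray  # (n_sections, n_semilandmarks), mm
    levels: np.ndarray
    ray_angles: np.ndarray

    @property
    def scaled(self) -> np.ndarray:
        """Min-max normalized to [0, 1]; a constant map scales to 0.5."""
        lo, hi = float(self.matrix.min()), float(self.matrix.max())
        if hi - lo < 1e-12:
            return np.full_like(self.matrix, 0.5)
        return (self.matrix - lo) / (hi - lo)

    #: Rendering convention for exported heat maps.
    color_convention = "high thickness = blue, low thickness = red"


def build_cohort_table(
    results: dict[str, tuple[str, list[SectionProperties]]],
    config: SamplingConfig,
    failures: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Flatten per-specimen section properties into a tidy long table.

    ``results`` maps specimen_id -> (group, per-level SectionProperties in
    level order).  Failed specimens are carried in ``failures`` (id ->
    reason) and recorded in the table attrs, never silently dropped.
    """
    from .sectioning import section_levels

    levels = section_levels(config)
    rows = []
    for sid, (group, props) in results.items():
        if len(props) != config.n_sections:
            raise ValidationError(
                f"specimen {sid}: {len(props)} sections, expected "
                f"{config.n_sections} (mixed configs?)"
            )
        for idx, (level, sp) in enumerate(zip(levels, props)):
            d = sp.as_dict()
            for name in COMPARISON_PROPERTIES:
                rows.append({
                    "specimen_id": sid,
                    "group": group,
                    "level_index": idx,
                    "level_fraction": float(level),
                    "property_name": name,
                    "value": d[name],
                })
    table = pd.DataFrame(rows)
    table.attrs["failures"] = dict(failures or {})
    table.attrs["config"] = config
    return table


def _nearest_level(table: pd.DataFrame, level: float) -> float:
    levels = np.sort(table["level_fraction"].unique())
    return float(levels[np.argmin(np.abs(levels - level))])


def group_compare(
    table: pd.DataFrame,
    property_name: str,
    level: float,
    test: str = "welch",
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-sample comparison of per-specimen values at the nearest level."""
    if test not in TESTS:
        raise ValidationError(f"test must be one of {TESTS}")
    lv = _nearest_level(table, level)
    sub = table[(table["property_name"] == property_name)
                & (table["level_fraction"] == lv)]
    healthy = sub.loc[sub["group"] == "healthy", "value"].to_numpy(float)
    osteo = sub.loc[sub["group"] == "osteoporosis", "value"].to_numpy(float)
    if len(healthy) < 2 or len(osteo) < 2:
        raise ValidationError(
            f"need >= 2 specimens per group at level {lv} "
            f"(got {len(healthy)} healthy, {len(osteo)} osteoporotic)"
        )
    mh, mo = float(np.mean(healthy)), float(np.mean(osteo))
    if np.ptp(np.concatenate([healthy, osteo])) < 1e-300:
        statistic, p = 0.0, 1.0  # identical data: no evidence either way
    elif test == "welch":
        res = stats.ttest_ind(healthy, osteo, equal_var=False)
        statistic, p = float(res.statistic), float(res.pvalue)
        if math.isnan(p):  # zero variance in both groups, unequal means
            statistic, p = math.inf, 0.0
    else:
        res = stats.mannwhitneyu(healthy, osteo, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        statistic, p = float(res.statistic), float(res.pvalue)
        if math.isnan(p):
            statistic, p = float(res.statistic), 1.0
    ratio = 100.0 * mo / mh if mh != 0 else math.nan
    return GroupComparison(
        property_name=property_name,
        level_fraction=lv,
        mean_healthy=mh,
        mean_osteo=mo,
        ratio_percent=ratio,
        test_name="welch_t" if test == "welch" else "mann_whitney_u",
        statistic=statistic,
        p_value=p,
        significant=bool(p < alpha),
        n_healthy=len(healthy),
        n_osteo=len(osteo),
    )


def compare_all(
    table: pd.DataFrame,
    levels=HEADLINE_LEVELS,
    test: str = "welch",
    alpha: float = 0.05,
    fdr: bool = False,
    properties=COMPARISON_PROPERTIES,
) -> pd.DataFrame:
    """Comparisons for every property at every requested level.

    With ``fdr=True`` the significance flags are recomputed from
    Benjamini-Hochberg adjusted p-values (off by default).
    """
    recs = [group_compare(table, p, lv, test=test, alpha=alpha).__dict__
            for p in properties for lv in levels]
    out = pd.DataFrame(recs)
    if fdr:
        adj = stats.false_discovery_control(out["p_value"].to_numpy())
        out["p_adjusted"] = adj
        out["significant"] = adj < alpha
    return out


def thickness_map(
    specimen_id: str,
    group: str,
    sections: list[CrossSection],
) -> ThicknessMap:
    """Assemble the (level, ray) thickness matrix for one processed specimen."""
    if not sections:
        raise ValidationError("no sections given")
    mats, levels = [], []
    for s in sections:
        if s.periosteal_slm is None:
            raise ValidationError(f"section at level {s.level} has no semilandmarks")
        mats.append(radial_thickness(s))
        levels.append(s.level)
    return ThicknessMap(
        specimen_id=specimen_id,
        group=group,
        matrix=np.vstack(mats),
        levels=np.asarray(levels),
        ray_angles=np.asarray(sections[0].ray_angles),
    )


def assign_sectors(ray_angles: np.ndarray) -> np.ndarray:
    """Sector name per ray: quadrants centred on +x (lateral), +y (anterior),
    -x (medial), -y (posterior)."""
    centers = {"lateral": 0.0, "anterior": 0.5 * np.pi,
               "medial": np.pi, "posterior": 1.5 * np.pi}
    out = np.empty(len(ray_angles), dtype=object)
    for i, ang in enumerate(ray_angles):
        best = min(centers, key=lambda n: abs(
            (ang - centers[n] + np.pi) % (2 * np.pi) - np.pi))
        out[i] = best
    return out


def regional_contrast(
    maps: list[ThicknessMap],
    level_band: tuple[float, float] = (0.20, 0.45),
    test: str = "welch",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-sector mean thickness difference (healthy minus osteoporotic).

    Each specimen contributes its mean thickness over the level band per
    anatomical sector; groups are then compared sector by sector.
    """
    lo, hi = level_band
    if not maps:
        raise ValidationError("no thickness maps given")
    sectors = assign_sectors(maps[0].ray_angles)
    per_spec = {name: {"healthy": [], "osteoporosis": []} for name in SECTOR_NAMES}
    for m in maps:
        in_band = (m.levels >= lo - 1e-12) & (m.levels <= hi + 1e-12)
        if not np.any(in_band):
            raise ValidationError("level band contains no sampled sections")
        for name in SECTOR_NAMES:
            cols = sectors == name
            if not np.any(cols):
                raise ValidationError(f"sector {name!r} contains no rays")
            per_spec[name][m.group].append(float(np.mean(m.matrix[np.ix_(in_band, cols)])))
    rows = []
    for name in SECTOR_NAMES:
        h = np.asarray(per_spec[name]["healthy"])
        o = np.asarray(per_spec[name]["osteoporosis"])
        row = {"sector": name,
               "mean_healthy": float(np.mean(h)) if len(h) else math.nan,
               "mean_osteo": float(np.mean(o)) if len(o) else math.nan}
        row["difference"] = row["mean_healthy"] - row["mean_osteo"]
        if len(h) >= 2 and len(o) >= 2:
            if np.ptp(np.concatenate([h, o])) < 1e-300:
                row["p_value"] = 1.0
            elif test == "welch":
                row["p_value"] = float(stats.ttest_ind(h, o, equal_var=False).pvalue)
            else:
                row["p_value"] = float(stats.mannwhitneyu(
                    h, o, alternative="two-sided").pvalue)
            row["significant"] = row["p_value"] < alpha
        else:
            row["p_value"] = math.nan
            row["significant"] = False
        rows.append(row)
    return pd.DataFrame(rows)


def render_heatmap(tmap: ThicknessMap, path) -> None:
    """Write a PNG heat map of scaled thickness (blue = thick, red = thin).

    Requires matplotlib (optional dependency); levels on the y axis
    (proximal up), rays on the x axis.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(tmap.scaled, aspect="auto", cmap="RdYlBu", origin="lower",
                   extent=[0, 360, tmap.levels[0] * 100, tmap.levels[-1] * 100],
                   vmin=0.0, vmax=1.0)
    ax.set_xlabel("ray angle from lateral (+x), degrees")
    ax.set_ylabel("% biomechanical length")
    ax.set_title(f"{tmap.specimen_id} ({tmap.group}) scaled cortical thickness")
    fig.colorbar(im, ax=ax, label="scaled thickness (1 = thick)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def summarize_run(comparisons: pd.DataFrame) -> dict:
    """Machine-readable headline summary.

    Per property x level: group means, ratio of means (percent), and the
    significance flag; plus the min/max ratio across levels per property.
    Degrades gracefully when comparisons are absent (e.g. one-group input).
    """
    summary: dict = {"levels": [], "properties": {}, "ratio_ranges": {}}
    if comparisons is None or comparisons.empty:
        summary["comparisons_available"] = False
        return summary
    summary["comparisons_available"] = True
    summary["levels"] = sorted(comparisons["level_fraction"].unique().tolist(),
                               reverse=True)
    for name, grp in comparisons.groupby("property_name"):
        entries = []
        for _, r in grp.sort_values("level_fraction", ascending=False).iterrows():
            entries.append({
                "level_fraction": float(r["level_fraction"]),
                "mean_healthy": float(r["mean_healthy"]),
                "mean_osteo": float(r["mean_osteo"]),
                "ratio_percent": float(r["ratio_percent"]),
                "p_value": float(r["p_value"]),
                "significant": bool(r["significant"]),
            })
        summary["properties"][name] = entries
        ratios = grp["ratio_percent"].to_numpy(float)
        finite = ratios[np.isfinite(ratios)]
        if len(finite):
            summary["ratio_ranges"][name] = [float(np.min(finite)),
                                             float(np.max(finite))]
    return summary
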