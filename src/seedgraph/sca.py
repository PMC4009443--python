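"""Seed correlation analysis over node-table (or voxel-like) geometries.

The stages mirror the classical resting-state workflow: average the
signals inside a spherical seed region, correlate that seed signal with
every other unit, Fisher-transform, run a one-sample group test on the z
maps, threshold and cluster the group map, and turn cluster peaks into
spherical network nodes.  Geometry is a table of unit positions in mm;
connectivity for clustering is distance-based, which covers both node
tables (link radius) and regular voxel grids (radius = voxel size times
sqrt(3) reproduces 26-connectivity).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .panel import TimeSeriesPanel
from .preprocess import fisher_z

__all__ = [
    "ROISpec",
    "StatMap",
    "tal2mni",
    "mni2tal",
    "extract_seed_signal",
    "seed_correlation_map",
    "group_inference",
    "threshold_and_cluster",
    "build_nodes",
    "template_match",
    "geometry_adjacency",
    "read_roi_table",
    "write_roi_table",
]

# Brett's piecewise-linear MNI -> Talairach transform: a small pitch
# rotation combined with axis zooms, one matrix above the AC plane and one
# below it.
_MNI2TAL_ABOVE = np.array([
    [0.9900, 0.0, 0.0],
    [0.0, 0.9688, 0.0460],
    [0.0, -0.0485, 0.9189],
])
_MNI2TAL_BELOW = np.array([
    [0.9900, 0.0, 0.0],
    [0.0, 0.9688, 0.0420],
    [0.0, -0.0485, 0.8390],
])
_TAL2MNI_ABOVE = np.linalg.inv(_MNI2TAL_ABOVE)
_TAL2MNI_BELOW = np.linalg.inv(_MNI2TAL_BELOW)


def mni2tal(coord: Sequence[float]) -> np.ndarray:
    """MNI (mm) to Talairach (mm); branch chosen by the MNI z sign."""
    c = np.asarray(coord, dtype=float)
    if c.shape != (3,):
        raise ValueError("coordinate must be a 3-vector")
    M = _MNI2TAL_ABOVE if c[2] >= 0 else _MNI2TAL_BELOW
    return M @ c

def tal2mni(coord: Sequence[float]) -> np.ndarray:
    """Talairach (mm) to MNI (mm), the exact inverse of :func:`mni2tal`.

    The above/below-AC branch is selected self-consistently: each inverse
    matrix is tried and the one whose output z sign matches its branch is
    kept (above-AC wins at z = 0 or if neither branch is consistent).
    """
    c = np.asarray(coord, dtype=float)
    if c.shape != (3,):
        raise ValueError("coordinate must be a 3-vector")
    above = _TAL2MNI_ABOVE @ c
    if above[2] >= 0:
        return above
    below = _TAL2MNI_BELOW @ c
    if below[2] < 0:
        return below
    return above


@dataclasses.dataclass
class ROISpec:
    """A spherical region of interest in a standard space."""

    label: str
    center_mm: tuple[float, float, float]
    radius_mm: float = 4.0
    space: str = "MNI"

    def __post_init__(self) -> None:
        self.center_mm = tuple(float(v) for v in self.center_mm)
        if len(self.center_mm) != 3:
            raise ValueError("center_mm must be a 3-vector")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")
        if self.space not in ("MNI", "Talairach"):
            raise ValueError("space must be 'MNI' or 'Talairach'")

    def to_mni(self) -> "ROISpec":
        if self.space == "MNI":
            return self
        return ROISpec(self.label, tuple(tal2mni(self.center_mm)),
                       self.radius_mm, "MNI")


@dataclasses.dataclass
class StatMap:
    """Per-unit statistic values over a geometry."""

    values: np.ndarray
    unit_ids: list[str]
    kind: str  # r | z | t | p

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[-1] != len(self.unit_ids):
            raise ValueError("values and unit_ids disagree in length")
        if self.kind not in ("r", "z", "t", "p"):
            raise ValueError(f"unknown statistic kind {self.kind!r}")
        if self.kind == "p":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("p-kind values must lie in [0, 1]")


def read_roi_table(path) -> list[ROISpec]:
    df = pd.read_csv(path, sep="\t")
    required = {"label", "x_mm", "y_mm", "z_mm", "radius_mm", "space"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ROI table missing columns: {sorted(missing)}")
    return [
        ROISpec(str(r.label), (r.x_mm, r.y_mm, r.z_mm), r.radius_mm, r.space)
        for r in df.itertuples()
    ]


def write_roi_table(rois: Sequence[ROISpec], path) -> None:
    pd.DataFrame(
        [
            {"label": r.label, "x_mm": r.center_mm[0], "y_mm": r.center_mm[1],
             "z_mm": r.center_mm[2], "radius_mm": r.radius_mm, "space": r.space}
            for r in rois
        ]
    ).to_csv(path, sep="\t", index=False)


def _coords(geometry: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    required = {"node", "x_mm", "y_mm", "z_mm"}
    missing = required - set(geometry.columns)
    if missing:
        raise ValueError(f"geometry table missing columns: {sorted(missing)}")
    ids = [str(n) for n in geometry["node"]]
    xyz = geometry[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    return ids, xyz


def extract_seed_signal(
    panel: TimeSeriesPanel, roi: ROISpec, geometry: pd.DataFrame
) -> tuple[np.ndarray, int]:
    """Mean signal over all units within the seed sphere, per subject.

    Returns ``(signal, n_units)`` where signal has shape
    (n_subjects, n_timepoints).  Talairach seeds are converted to MNI
    before the distance test.
    """
    roi = roi.to_mni()
    ids, xyz = _coords(geometry)
    dist = np.linalg.norm(xyz - np.asarray(roi.center_mm), axis=1)
    inside = np.where(dist <= roi.radius_mm)[0]
    if inside.size == 0:
        raise ValueError(f"no units within {roi.radius_mm} mm of ROI {roi.label!r}")
    idx = [panel.node_index(ids[i]) for i in inside]
    return panel.data[:, idx, :].mean(axis=1), int(inside.size)


def seed_correlation_map(
    panel: TimeSeriesPanel, seed_signal: np.ndarray, clip: bool = True
) -> list[StatMap]:
    """Per-subject Fisher-z seed correlation map over all panel nodes.

    Units with zero variance get NaN (flagged missing, never silently 0).
    """
    seed_signal = np.atleast_2d(np.asarray(seed_signal, dtype=float))
    if seed_signal.shape != (panel.n_subjects, panel.n_timepoints):
        raise ValueError("seed signal must be (n_subjects, n_timepoints)")
    maps = []
    for s in range(panel.n_subjects):
        seed = seed_signal[s]
        if seed.std() <= 1e-12 * (np.abs(seed).max() + 1.0):
            raise ValueError(f"constant seed signal for subject {s}")
        X = panel.data[s]
        sd = X.std(axis=1)
        flat = sd <= 1e-12 * (np.abs(X).max(axis=1) + 1.0)
        seed_c = seed - seed.mean()
        Xc = X - X.mean(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc @ seed_c) / (
                np.linalg.norm(Xc, axis=1) * np.linalg.norm(seed_c)
            )
        r[flat] = np.nan
        z = np.full_like(r, np.nan)
        ok = np.isfinite(r)
        z[ok] = fisher_z(r[ok], clip=clip)
        maps.append(StatMap(z, list(panel.node_ids), "z"))
    return maps


def group_inference(
    maps: Sequence[StatMap], missing_policy: str = "pairwise"
) -> tuple[StatMap, StatMap, int]:
    """One-sample t-test of per-subject z maps against zero.

    Returns (t map, two-sided p map, nominal degrees of freedom
    ``n_subjects - 1``).  Units missing in some subjects are handled per
    ``missing_policy``: "pairwise" uses the available subjects,
    "drop" marks the unit NaN.  Zero within-unit variance yields NaN p
    (degenerate, flagged).
    """
    if len(maps) < 3:
        raise ValueError("group inference needs at least 3 subjects")
    if missing_policy not in ("pairwise", "drop"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    unit_ids = maps[0].unit_ids
    Z = np.stack([m.values for m in maps])
    n_units = Z.shape[1]
    t = np.full(n_units, np.nan)
    p = np.full(n_units, np.nan)
    for j in range(n_units):
        col = Z[:, j]
        ok = np.isfinite(col)
        if not ok.all() and missing_policy == "drop":
            continue
        col = col[ok]
        if col.size < 3 or col.std(ddof=1) <= 1e-12 * (np.abs(col).max() + 1.0):
            continue
        res = scipy.stats.ttest_1samp(col, 0.0)
        t[j], p[j] = res.statistic, res.pvalue
    return (StatMap(t, list(unit_ids), "t"),
            StatMap(p, list(unit_ids), "p"),
            len(maps) - 1)


def geometry_adjacency(geometry: pd.DataFrame, link_radius_mm: float) -> np.ndarray:
    """Boolean adjacency: units whose mutual distance is <= the link radius."""
    _, xyz = _coords(geometry)
    d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=2)
    adj = (d <= link_radius_mm) & (d > 0)
    return adj


def _connected_components(members: np.ndarray, adj: np.ndarray) -> list[list[int]]:
    """Components of the subgraph induced by ``members`` (unit indices)."""
    member_set = set(members.tolist())
    seen: set[int] = set()
    comps = []
    for start in members:
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.where(adj[u])[0]:
                if v in member_set and v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


def _height_pass(p_values: np.ndarray, peak_rule: dict) -> np.ndarray:
    kind = peak_rule.get("kind", "fdr")
    finite = np.isfinite(p_values)
    passed = np.zeros_like(finite)
    if kind == "fdr":
        q = peak_rule.get("q", 0.01)
        if finite.any():
            rej, *_ = multipletests(p_values[finite], alpha=q, method="fdr_bh")
            passed[finite] = rej
    elif kind == "p":
        alpha = peak_rule.get("p", 0.01)
        passed[finite] = p_values[finite] < alpha
    else:
        raise ValueError(f"unknown height-threshold kind {kind!r}")
    return passed


def _clusters_at(
    t: np.ndarray, passed: np.ndarray, adj: np.ndarray
) -> list[tuple[int, list[int]]]:
    """Signed clusters among supra-threshold units: list of (sign, members)."""
    out = []
    for sign in (1, -1):
        members = np.where(passed & (np.sign(t) == sign))[0]
        if members.size:
            out.extend((sign, c) for c in _connected_components(members, adj))
    return out


def threshold_and_cluster(
    tmap: StatMap,
    pmap: StatMap,
    geometry: pd.DataFrame,
    peak_rule: dict | None = None,
    extent_rule: dict | None = None,
    link_radius_mm: float = 15.0,
    subject_maps: Sequence[StatMap] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Threshold a group map and extract signed clusters.

    Height threshold per ``peak_rule`` ({"kind": "fdr", "q": ...} or
    {"kind": "p", "p": ...}); positive and negative t are clustered
    separately over distance-based connectivity.  The extent rule is
    either a fixed minimum size ({"kind": "k", "min_size": ...}) or a
    sign-flip permutation null on maximum cluster size
    ({"kind": "permutation", "n_perm": ..., "p": ...}; requires the
    per-subject maps).  Returns a table with one row per surviving
    cluster: label, sign, size, peak coordinate and statistic (peak = the
    maximum-|t| member, ties broken by smallest (x, y, z)).
    """
    peak_rule = peak_rule or {"kind": "fdr", "q": 0.01}
    extent_rule = extent_rule or {"kind": "k", "min_size": 1}
    ids, xyz = _coords(geometry)
    if ids != list(tmap.unit_ids):
        raise ValueError("geometry and stat map unit ids disagree")
    adj = geometry_adjacency(geometry, link_radius_mm)
    t, p = tmap.values, pmap.values
    passed = _height_pass(p, peak_rule)
    clusters = _clusters_at(t, passed, adj)

    if extent_rule.get("kind", "k") == "k":
        min_size = int(extent_rule.get("min_size", 1))
    elif extent_rule["kind"] == "permutation":
        if subject_maps is None:
            raise ValueError("permutation extent rule needs subject_maps")
        min_size = _permutation_extent(
            subject_maps, adj, peak_rule,
            n_perm=int(extent_rule.get("n_perm", 999)),
            alpha=float(extent_rule.get("p", 0.01)),
            seed=seed,
        )
    else:
        raise ValueError(f"unknown extent rule {extent_rule['kind']!r}")

    rows = []
    for sign, comp in clusters:
        if len(comp) < min_size:
            continue
        comp_arr = np.asarray(comp)
        best = np.abs(t[comp_arr]).max()
        tied = comp_arr[np.abs(t[comp_arr]) == best]
        peak = tied[np.lexsort((xyz[tied, 2], xyz[tied, 1], xyz[tied, 0]))][0]
        rows.append({
            "sign": "positive" if sign > 0 else "negative",
            "size_k": len(comp),
            "peak_unit": ids[peak],
            "peak_x_mm": xyz[peak, 0],
            "peak_y_mm": xyz[peak, 1],
            "peak_z_mm": xyz[peak, 2],
            "peak_stat": t[peak],
            "members": ",".join(ids[i] for i in comp),
        })
    rows.sort(key=lambda r: -r["size_k"])
    table = pd.DataFrame(
        rows, columns=["sign", "size_k", "peak_unit", "peak_x_mm",
                       "peak_y_mm", "peak_z_mm", "peak_stat", "members"],
    )
    table.insert(0, "label", [f"cluster{i + 1:02d}" for i in range(len(table))])
    return table


def _permutation_extent(
    subject_maps: Sequence[StatMap],
    adj: np.ndarray,
    peak_rule: dict,
    n_perm: int,
    alpha: float,
    seed: int,
) -> int:
    """Sign-flip permutation null for the maximum cluster size.

    Each unit is demeaned across subjects before flipping, so the null
    reflects noise-only cluster sizes even when a true effect is present
    in many units (flipping raw maps with a strong common signal would
    inflate the null and swallow genuine clusters).  Returns the minimum
    cluster size whose probability under that null is below ``alpha``
    (the (1 - alpha) quantile of the max-cluster-size distribution, plus
    one).
    """
    rng = np.random.default_rng(seed)
    Z = np.stack([m.values for m in subject_maps])
    with np.errstate(invalid="ignore"):
        Z = Z - np.nanmean(Z, axis=0, keepdims=True)
    n_sub = Z.shape[0]
    max_sizes = np.zeros(n_perm, dtype=int)
    for b in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=n_sub)[:, None]
        Zb = Z * flips
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(Zb, axis=0)
            sd = np.nanstd(Zb, axis=0, ddof=1)
            n_ok = np.sum(np.isfinite(Zb), axis=0)
            tb = mean / (sd / np.sqrt(n_ok))
        pb = 2 * scipy.stats.t.sf(np.abs(tb), df=np.maximum(n_ok - 1, 1))
        pb[~np.isfinite(tb)] = np.nan
        passed = _height_pass(pb, peak_rule)
        sizes = [len(c) for _, c in _clusters_at(tb, passed, adj)]
        max_sizes[b] = max(sizes) if sizes else 0
    return int(np.quantile(max_sizes, 1 - alpha, method="higher")) + 1


def build_nodes(
    clusters: pd.DataFrame,
    radius_mm: float = 4.0,
    replacements: Sequence[ROISpec] = (),
) -> list[ROISpec]:
    """Turn cluster peaks into spherical nodes, honouring seed replacements.

    One sphere per cluster at its peak, ordered by cluster size
    descending.  Any node whose sphere contains the centre of a
    replacement seed is removed and the replacement seed(s) inserted in
    its place (each replacement is inserted once).
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be > 0")
    peaks = clusters[["peak_x_mm", "peak_y_mm", "peak_z_mm"]].to_numpy(float)
    if len(peaks) != len({tuple(p) for p in peaks}):
        raise ValueError("duplicate cluster peak centers")
    order = np.argsort(-clusters["size_k"].to_numpy())
    reps = [r.to_mni() for r in replacements]
    out: list[ROISpec] = []
    inserted: set[str] = set()
    for rank, i in enumerate(order):
        center = tuple(peaks[i])
        hits = [r for r in reps
                if np.linalg.norm(np.subtract(r.center_mm, center)) <= radius_mm]
        if hits:
            for r in hits:
                if r.label not in inserted:
                    inserted.add(r.label)
                    out.append(r)
        else:
            out.append(ROISpec(
                f"node_{clusters['label'].iloc[i]}", center, radius_mm, "MNI"
            ))
    labels = [r.label for r in out]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate node labels after replacement")
    return out


def template_match(
    stat_map: StatMap, template: StatMap, n_candidates: int = 1
) -> tuple[float, float]:
    """Spatial correlation of a map with a template mask.

    Pearson r over the units finite in both maps; the two-sided p-value
    is Bonferroni-corrected for the number of candidate maps compared.
    """
    if list(stat_map.unit_ids) != list(template.unit_ids):
        raise ValueError("map and template must share a geometry")
    a, b = stat_map.values, template.values
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 common finite units")
    r, p = scipy.stats.pearsonr(a[ok], b[ok])
    return float(r), float(min(1.0, p * n_candidates))
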