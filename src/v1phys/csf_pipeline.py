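"""Contrast-sensitivity pipeline: traces + epochs -> ordinal categories.

Per presentation, the evoked response is the mean dF/F over the stimulus
frames minus the mean over the immediately preceding baseline frames.  A
cell is responsive to a (SF, contrast) stimulus when a one-sided sign-flip
permutation test of its evoked responses against zero gives p < alpha
(exhaustive over all sign assignments for <= 10 repeats) AND the mean
evoked dF/F reaches a minimum amplitude.  Contrast sensitivity at an SF is
log2(1 / smallest responsive grid contrast), with no monotonic fill-in;
cells responsive at no contrast for an SF get the category "NR".

Frame conventions: indices are 0-based; windows are half-open
[onset, offset).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import percentile_filter

__all__ = [
    "ALPHA",
    "RESPONSE_MARGIN",
    "FluorescenceDataset",
    "compute_dff",
    "validate_epochs",
    "trial_responses",
    "classify_responsive",
    "min_responsive_contrast",
    "build_cs_table",
    "population_csf",
    "proportion_responding",
    "sensitivity_levels",
    "ordinal_dataset_from_cs_table",
]

#: default significance level of the responsiveness permutation test
ALPHA = 0.05
#: default minimum mean evoked dF/F for a response to count
RESPONSE_MARGIN = 0.05

_NR = "NR"


@dataclass
class FluorescenceDataset:
    """Cells-by-frames fluorescence matrix with acquisition metadata."""

    traces: np.ndarray  # (n_cells, n_frames)
    frame_rate_hz: float
    animal: str
    genotype: str
    cell_ids: Optional[Sequence[str]] = None
    is_dff: bool = True
    fov: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if np.isnan(self.traces).any():
            raise ValueError("NaN frames in fluorescence traces")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame rate must be positive")
        if self.cell_ids is None:
            self.cell_ids = [f"{self.animal}_c{i}" for i in range(self.traces.shape[0])]
        elif len(self.cell_ids) != self.traces.shape[0]:
            raise ValueError("cell_ids length mismatch")

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]


def compute_dff(
    traces: np.ndarray,
    frame_rate_hz: float,
    mode: str = "raw",
    window_s: float = 30.0,
    percentile: float = 10.0,
) -> np.ndarray:
    """dF/F = (F - F0)/F0 with F0 a rolling low-percentile baseline.

    ``mode='dff'`` passes the input through unchanged.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if mode == "dff":
        return traces
    if mode != "raw":
        raise ValueError("mode must be 'raw' or 'dff'")
    w = max(1, int(round(window_s * frame_rate_hz)))
    f0 = percentile_filter(traces, percentile, size=(1, w), mode="nearest")
    bad = np.flatnonzero((f0 <= 0).any(axis=1))
    if len(bad):
        raise ValueError(f"non-positive baseline F0 for cell rows {bad.tolist()}")
    return (traces - f0) / f0


_EPOCH_COLUMNS = ("onset_frame", "offset_frame", "sf_cpd", "contrast", "repeat")


def validate_epochs(epochs: pd.DataFrame, n_frames: Optional[int] = None) -> pd.DataFrame:
    """Schema/consistency checks; returns the epochs sorted by onset."""
    missing = [c for c in _EPOCH_COLUMNS if c not in epochs.columns]
    if missing:
        raise ValueError(f"epochs table missing columns: {missing}")
    ep = epochs.sort_values("onset_frame").reset_index(drop=True)
    if (ep["offset_frame"] <= ep["onset_frame"]).any():
        raise ValueError("epochs with offset_frame <= onset_frame")
    if (ep["onset_frame"] < 0).any():
        raise ValueError("negative onset frames")
    if n_frames is not None:
        bad = ep.index[ep["offset_frame"] > n_frames].tolist()
        if bad:
            raise ValueError(f"epochs beyond trace length ({n_frames} frames): rows {bad}")
    overlap = np.flatnonzero(
        ep["onset_frame"].values[1:] < ep["offset_frame"].values[:-1]
    )
    if len(overlap):
        raise ValueError(f"overlapping epochs at sorted rows {(overlap + 1).tolist()}")
    counts = ep.groupby(["sf_cpd", "contrast"]).size()
    if counts.nunique() > 1:
        warnings.warn("unequal presentation counts across (sf, contrast) stimuli")
    return ep


def trial_responses(dataset: FluorescenceDataset, epochs: pd.DataFrame) -> pd.DataFrame:
    """Per-cell, per-presentation evoked responses.

    evoked = mean dF/F over [onset, offset) - mean over the immediately
    preceding baseline window [previous offset, onset).
    """
    ep = validate_epochs(epochs, dataset.n_frames)
    traces = dataset.traces
    evoked = np.empty((dataset.n_cells, len(ep)))
    keep = np.ones(len(ep), dtype=bool)
    prev_off = 0
    for i, r in ep.iterrows():
        on, off = int(r["onset_frame"]), int(r["offset_frame"])
        b0 = prev_off
        prev_off = off
        if on <= b0:
            warnings.warn(f"presentation {i} has no preceding baseline frames; dropped")
            keep[i] = False
            continue
        evoked[:, i] = traces[:, on:off].mean(axis=1) - traces[:, b0:on].mean(axis=1)
    ep = ep.loc[keep]
    evoked = evoked[:, keep]
    n_cells, n_pres = evoked.shape
    out = pd.DataFrame(
        {
            "cell": np.repeat(dataset.cell_ids, n_pres),
            "animal": dataset.animal,
            "genotype": dataset.genotype,
            "sf_cpd": np.tile(ep["sf_cpd"].values, n_cells),
            "contrast": np.tile(ep["contrast"].values, n_cells),
            "repeat": np.tile(ep["repeat"].values, n_cells),
            "evoked": evoked.ravel(),
        }
    )
    return out


def _sign_matrix(n: int) -> np.ndarray:
    """All 2^n sign assignments, one per row (+1 first = identity)."""
    bits = (np.arange(2 ** n)[:, None] >> np.arange(n)[None, :]) & 1
    return 1.0 - 2.0 * bits


def permutation_pvalue(values: np.ndarray, rng=None, max_exact_n: int = 10, n_perm: int = 10_000) -> float:
    """One-sided sign-flip permutation p-value for mean > 0 (exact for small n)."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    obs = x.mean()
    if n <= max_exact_n:
        perm = _sign_matrix(n) @ x / n
    else:
        rng = np.random.default_rng(rng)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        perm = np.concatenate([[obs], signs @ x / n])
    return float(np.mean(perm >= obs - 1e-12))


def classify_responsive(
    evoked_values: np.ndarray,
    alpha: float = ALPHA,
    min_amplitude: float = RESPONSE_MARGIN,
    **perm_kwargs,
) -> bool:
    """Responsive iff permutation p < alpha AND mean evoked >= min_amplitude."""
    x = np.asarray(evoked_values, dtype=float)
    if len(x) < 3:
        warnings.warn("fewer than 3 repeats: responsiveness undefined, treated nonresponsive")
        return False
    if x.mean() < min_amplitude:
        return False
    return permutation_pvalue(x, **perm_kwargs) < alpha


def min_responsive_contrast(responsive_by_contrast: dict) -> Optional[float]:
    """Smallest grid contrast classified responsive; None when none are.

    No monotonic fill-in: intermediate nonresponsive contrasts are ignored.
    """
    resp = [c for c, r in responsive_by_contrast.items() if r]
    return min(resp) if resp else None


def build_cs_table(
    dataset: FluorescenceDataset,
    epochs: pd.DataFrame,
    alpha: float = ALPHA,
    min_amplitude: float = RESPONSE_MARGIN,
    dff_mode: Optional[str] = None,
) -> pd.DataFrame:
    """Per-cell, per-SF ordinal contrast-sensitivity categories.

    A cell is flagged visually responsive iff it is responsive to at least
    one of the (SF, contrast) stimuli; only such cells feed downstream
    CSF / ordinal-model analyses.
    """
    if dff_mode is None:
        dff_mode = "dff" if dataset.is_dff else "raw"
    dff = compute_dff(dataset.traces, dataset.frame_rate_hz, mode=dff_mode)
    ds = FluorescenceDataset(
        traces=dff,
        frame_rate_hz=dataset.frame_rate_hz,
        animal=dataset.animal,
        genotype=dataset.genotype,
        cell_ids=dataset.cell_ids,
        is_dff=True,
        fov=dataset.fov,
    )
    tr = trial_responses(ds, epochs)

    sfs = np.sort(tr["sf_cpd"].unique())
    contrasts = np.sort(tr["contrast"].unique())
    # (cell, sf, contrast) -> repeats vector; exact enumeration when feasible
    cube = (
        tr.groupby(["cell", "sf_cpd", "contrast"], sort=True)["evoked"]
        .apply(lambda v: v.to_numpy())
    )
    n_rep = len(cube.iloc[0])
    balanced = all(len(v) == n_rep for v in cube)
    means = np.array([v.mean() for v in cube])
    if balanced and 3 <= n_rep <= 10:
        E = np.stack(cube.to_numpy())  # (n_cell*n_sf*n_con, n_rep)
        S = _sign_matrix(n_rep)
        perm = E @ S.T / n_rep  # (rows, 2^n) exact enumeration
        pvals = (perm >= means[:, None] - 1e-12).mean(axis=1)
        responsive = (pvals < alpha) & (means >= min_amplitude)
    else:
        responsive = np.array(
            [classify_responsive(v, alpha=alpha, min_amplitude=min_amplitude) for v in cube]
        )

    resp_df = pd.DataFrame(
        {
            "cell": cube.index.get_level_values("cell"),
            "sf_cpd": cube.index.get_level_values("sf_cpd"),
            "contrast": cube.index.get_level_values("contrast"),
            "responsive": responsive,
        }
    )
    rows = []
    vr = resp_df.groupby("cell")["responsive"].any()
    for (cell, sf), grp in resp_df.groupby(["cell", "sf_cpd"], sort=True):
        cmin = min_responsive_contrast(dict(zip(grp["contrast"], grp["responsive"])))
        rows.append(
            {
                "cell": cell,
                "animal": dataset.animal,
                "genotype": dataset.genotype,
                "sf_cpd": sf,
                "min_responsive_contrast": np.nan if cmin is None else cmin,
                "contrast_sensitivity": np.nan if cmin is None else float(np.log2(1.0 / cmin)),
                "category": _NR if cmin is None else f"{np.log2(1.0 / cmin):.4f}",
                "visually_responsive": bool(vr.loc[cell]),
            }
        )
    return pd.DataFrame(rows)


def population_csf(cs_table: pd.DataFrame, group_by=("animal",)) -> pd.DataFrame:
    """Per group x SF: mean + IQR of contrast sensitivity over non-NR cells.

    NR cells are excluded from the mean/IQR (an ordinal mean including NR is
    undefined) and reported through ``fraction_nr`` instead.  Only visually
    responsive cells enter.
    """
    if cs_table.empty:
        raise ValueError("empty contrast-sensitivity table")
    tab = cs_table[cs_table["visually_responsive"]]
    group_by = list(group_by)
    rows = []
    for key, grp in tab.groupby(group_by + ["sf_cpd"], sort=True):
        key = key if isinstance(key, tuple) else (key,)
        vals = grp["contrast_sensitivity"].dropna()
        rec = dict(zip(group_by + ["sf_cpd"], key))
        rec.update(
            {
                "n_cells": len(grp),
                "fraction_nr": float(grp["contrast_sensitivity"].isna().mean()),
                "mean_sensitivity": float(vals.mean()) if len(vals) else np.nan,
                "q25": float(vals.quantile(0.25)) if len(vals) else np.nan,
                "q75": float(vals.quantile(0.75)) if len(vals) else np.nan,
            }
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def proportion_responding(cs_table: pd.DataFrame, sf_cpd: float, genotype: Optional[str] = None) -> float:
    """Share of visually responsive cohort cells with a non-NR category at ``sf_cpd``."""
    tab = cs_table[cs_table["visually_responsive"]]
    if genotype is not None:
        tab = tab[tab["genotype"] == genotype]
    cells = tab["cell"].nunique()
    if cells == 0:
        raise ValueError("empty cohort")
    at_sf = tab[np.isclose(tab["sf_cpd"], sf_cpd)]
    responding = at_sf.loc[at_sf["contrast_sensitivity"].notna(), "cell"].nunique()
    return responding / cells


def sensitivity_levels(contrast_grid: Sequence[float]) -> list:
    """Ordered category levels: NR below all numeric log2(1/c) levels."""
    numeric = sorted(float(np.log2(1.0 / c)) for c in contrast_grid)
    return [_NR] + numeric


def ordinal_dataset_from_cs_table(
    cs_table: pd.DataFrame,
    contrast_grid: Optional[Sequence[float]] = None,
    drop_nr: bool = False,
) -> pd.DataFrame:
    """Rows (cell, animal, genotype, sf, category index 1..K) for the CLMM.

    NR enters as the lowest level (1) unless ``drop_nr``.  Only visually
    responsive cells are included.
    """
    tab = cs_table[cs_table["visually_responsive"]].copy()
    if contrast_grid is not None:
        numeric = sorted(float(np.log2(1.0 / c)) for c in contrast_grid)
    else:
        numeric = sorted(tab["contrast_sensitivity"].dropna().unique())
    level_of = {round(v, 6): i + 2 for i, v in enumerate(numeric)}  # NR = 1

    def _lvl(x):
        if np.isnan(x):
            return 1
        key = round(float(x), 6)
        if key not in level_of:
            raise ValueError(f"sensitivity {x} not on the category grid")
        return level_of[key]

    tab["category"] = tab["contrast_sensitivity"].apply(_lvl)
    if drop_nr:
        tab = tab[tab["category"] > 1].copy()
        tab["category"] -= 1
    out = tab[["cell", "animal", "genotype", "sf_cpd", "category"]].rename(columns={"sf_cpd": "sf"})
    return out.reset_index(drop=True)
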