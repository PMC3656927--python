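"""Plate normalization, per-cell ratio curves, and assay-format comparison.

Raw bulk readouts are converted to percent of the plate-averaged vehicle
(DMSO) control, with blank (medium-only) background subtraction for the
absorbance/fluorescence assays (MTS, DNA dye) but not for ATP luminescence.
Fold-change ratio curves (proxy signal per cell relative to control) expose
the size/metabolism coupling that makes metabolic proxies diverge from
direct cell counts, and the total mitochondrial mass series (cell number x
mean per-cell MitoTracker intensity, renormalized to control) reconstructs
an ATP-like curve from imaging alone.

Format comparison flags a proxy assay against the cell-count reference when
log EC50 differs by more than 1 log unit or Emax by more than 25 percentage
points; censored entries (">-4.6", "<20") are treated as one-sided bounds
and flags are raised only when the bound guarantees the threshold is
exceeded.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from cycleplate.doseresponse import LogisticFit

__all__ = [
    "Censored",
    "NormalizedWell",
    "FormatComparison",
    "EC50_FLAG_THRESHOLD",
    "EMAX_FLAG_THRESHOLD",
    "normalize_readout",
    "normalize_wells",
    "ratio_curve",
    "mito_fold_change",
    "total_mito_mass",
    "compare_formats",
]

EC50_FLAG_THRESHOLD = 1.0    # log10 units
EMAX_FLAG_THRESHOLD = 25.0   # percentage points


@dataclass(frozen=True)
class Censored:
    """A censored fit value such as ``">-4.6"`` or ``"<20"``.

    ``op`` is ``">"`` (true value exceeds ``value``) or ``"<"`` (true value
    is below ``value``).
    """

    value: float
    op: str

    def __post_init__(self) -> None:
        if self.op not in ("<", ">"):
            raise ValueError("op must be '<' or '>'")

    @classmethod
    def parse(cls, text: str) -> "Censored":
        m = re.fullmatch(r"\s*([<>])\s*([+-]?\d*\.?\d+(?:[eE][+-]?\d+)?)\s*", text)
        if not m:
            raise ValueError(f"cannot parse censored value {text!r}")
        return cls(float(m.group(2)), m.group(1))

    @property
    def interval(self) -> tuple[float, float]:
        if self.op == ">":
            return (self.value, math.inf)
        return (-math.inf, self.value)


Bound = Union[float, Censored, str]


def _interval(v: Bound) -> tuple[float, float]:
    if isinstance(v, Censored):
        return v.interval
    if isinstance(v, str):
        return Censored.parse(v).interval
    return (float(v), float(v))


@dataclass(frozen=True)
class NormalizedWell:
    """One well's readout expressed as percent of the plate control."""

    well: str
    readout: str
    raw: float
    background: float
    pct_of_control: float


@dataclass(frozen=True)
class FormatComparison:
    """Discrepancy flags between a proxy assay fit and the cell-count fit."""

    compound: str
    delta_log_ec50: float       # proxy - count; nan when unbounded/censored
    delta_emax: float           # count - proxy; nan when unbounded/censored
    ec50_flag: bool
    emax_flag: bool
    reason: str = ""


def normalize_readout(
    raw: Sequence[float],
    control_raw: Sequence[float],
    blank_raw: Optional[Sequence[float]] = None,
    subtract_background: bool = False,
) -> tuple[np.ndarray, float]:
    """Percent-of-control values for one readout.

    When ``subtract_background`` is set, the mean of the blank (medium-only)
    wells is removed from every raw value before normalization — the MTS and
    DNA-dye convention; ATP luminescence is normalized without blanks.
    Returns ``(pct, background)``.
    """
    raw = np.asarray(raw, dtype=float)
    control_raw = np.asarray(control_raw, dtype=float)
    if control_raw.size < 2:
        raise ValueError("at least 2 control wells are required")
    if subtract_background:
        if blank_raw is None or len(blank_raw) == 0:
            raise ValueError("blank wells are required when subtract_background is set")
        background = float(np.mean(np.asarray(blank_raw, dtype=float)))
    else:
        background = 0.0
    ctrl_mean = float(np.mean(control_raw)) - background
    if ctrl_mean <= 0:
        raise ZeroDivisionError("control mean does not exceed background")
    return 100.0 * (raw - background) / ctrl_mean, background


#: Per-readout blank-subtraction convention: ATP has none, the
#: absorbance/fluorescence plate readers do.
DEFAULT_READOUTS: dict[str, bool] = {"atp": False, "mts": True, "cyquant": True}


def normalize_wells(
    wells: pd.DataFrame,
    readouts: Optional[dict[str, bool]] = None,
    count_col: Optional[str] = "count_truth",
) -> pd.DataFrame:
    """Normalize a simulator-schema well table to percent of control.

    Control wells are rows with ``is_control`` (or ``compound == "DMSO"``),
    blanks rows with ``is_blank`` (or ``compound == "BLANK"``).  Adds a
    ``<readout>_pct`` column per readout plus ``count_pct`` when
    ``count_col`` is present; blank rows are dropped from the result.
    """
    readouts = DEFAULT_READOUTS if readouts is None else readouts
    df = wells.copy()
    ctrl = df["is_control"] if "is_control" in df else df["compound"].eq("DMSO")
    blank = df["is_blank"] if "is_blank" in df else df["compound"].eq("BLANK")

    for col, subtract in readouts.items():
        pct, _ = normalize_readout(
            df[col].to_numpy(),
            df.loc[ctrl, col].to_numpy(),
            blank_raw=df.loc[blank, col].to_numpy() if subtract else None,
            subtract_background=subtract,
        )
        df[f"{col}_pct"] = pct
    if count_col is not None and count_col in df:
        pct, _ = normalize_readout(
            df[count_col].to_numpy(), df.loc[ctrl, count_col].to_numpy()
        )
        df["count_pct"] = pct
    return df.loc[~blank].reset_index(drop=True)


def ratio_curve(
    signal: pd.DataFrame,
    count: pd.DataFrame,
    conc_col: str = "conc_molar",
    pct_cols: tuple[str, str] = ("pct", "pct"),
    min_count_pct: float = 1.0,
) -> pd.DataFrame:
    """Fold change of the signal-to-count ratio versus concentration.

    ``signal`` and ``count`` are per-well tables with a concentration column
    and a percent-of-control column; replicates are averaged per
    concentration before the ratio is taken.  Both being percent of control,
    the ratio at vanishing concentration is 1 in expectation.
    Concentrations where the mean count drops below ``min_count_pct``
    (near-total kill) are omitted.
    """
    sig_col, cnt_col = pct_cols
    s = signal.groupby(conc_col, sort=True)[sig_col].mean()
    c = count.groupby(conc_col, sort=True)[cnt_col].mean()
    common = s.index.intersection(c.index)
    if len(common) == 0:
        raise ValueError("signal and count series share no concentrations")
    s, c = s.loc[common], c.loc[common]
    keep = c >= min_count_pct
    out = pd.DataFrame(
        {
            "conc_molar": common[keep],
            "log10_conc": np.log10(common[keep].astype(float)),
            "fold_change": (s[keep] / c[keep]).to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def mito_fold_change(cells: pd.DataFrame, control_wells: Sequence[str]) -> pd.Series:
    """Per-well mean MitoTracker intensity as fold of the control mean.

    The control reference is the mean of the control wells' per-well means
    (the plate-averaged DMSO control).
    """
    per_well = cells.groupby("well")["mito_int"].mean()
    ctrl = per_well.loc[[w for w in control_wells if w in per_well.index]]
    if len(ctrl) < 2:
        raise ValueError("at least 2 control wells with cells are required")
    return per_well / float(ctrl.mean())


def total_mito_mass(
    count_pct: pd.Series,
    mito_fold: pd.Series,
    control_wells: Sequence[str],
) -> pd.Series:
    """Total mitochondrial mass series: count x per-cell mito, percent of control.

    The per-well product of percent-of-control cell count and per-cell
    mitochondrial fold change is renormalized to the mean control product,
    yielding a percent-of-control series directly fittable by the 4PL
    machinery.
    """
    common = count_pct.index.intersection(mito_fold.index)
    if len(common) == 0:
        raise ValueError("count and mito series share no wells")
    product = count_pct.loc[common] * mito_fold.loc[common]
    ctrl = product.loc[[w for w in control_wells if w in product.index]]
    if len(ctrl) < 2:
        raise ValueError("at least 2 control wells are required")
    return 100.0 * product / float(ctrl.mean())


def _extract(fit):
    """Normalize a fit-like input to (ec50 bound, emax bound, attempted-valid).

    Accepts a :class:`LogisticFit`, an ``(ec50, emax)`` pair of plain or
    censored values (either element may be ``None``), a single value (taken
    as log EC50 only), or ``None`` (no valid fit).
    """
    if fit is None:
        return None, None, False
    if isinstance(fit, LogisticFit):
        if not fit.valid:
            return None, None, False
        return fit.log_ec50, fit.emax_pct_reduction, True
    if isinstance(fit, tuple):
        ec50, emax = fit
        return ec50, emax, True
    return fit, None, True


def _delta(a: Optional[Bound], b: Optional[Bound], threshold: float):
    """Bounds on ``b - a``; flag only when the bound guarantees |delta| > threshold."""
    if a is None or b is None:
        return math.nan, False
    alo, ahi = _interval(a)
    blo, bhi = _interval(b)
    d_lo, d_hi = blo - ahi, bhi - alo
    flag = d_lo > threshold or d_hi < -threshold
    return (d_lo if d_lo == d_hi else math.nan), bool(flag)


def compare_formats(
    count_fit: Union[LogisticFit, Bound, tuple, None],
    proxy_fit: Union[LogisticFit, Bound, tuple, None],
    compound: str = "",
) -> FormatComparison:
    """Flag EC50 / Emax discrepancies of a proxy assay against cell count.

    Accepts fitted :class:`LogisticFit` objects or published-table-style
    values: an ``(ec50, emax)`` pair whose elements are floats,
    :class:`Censored` bounds or strings like ``">-4.6"`` (a bare value is
    taken as log EC50).  With censored bounds a flag is raised only when the
    bound guarantees the threshold is exceeded.  An invalid proxy fit
    against a valid count fit raises both flags with reason
    ``"no valid fit"``.
    """
    c_ec50, c_emax, c_ok = _extract(count_fit)
    p_ec50, p_emax, p_ok = _extract(proxy_fit)

    if not c_ok:
        return FormatComparison(compound, math.nan, math.nan, False, False,
                                reason="no valid cell-count fit")
    if not p_ok:
        return FormatComparison(compound, math.nan, math.nan, True, True,
                                reason="no valid fit")

    delta_ec50, ec50_flag = _delta(c_ec50, p_ec50, EC50_FLAG_THRESHOLD)
    # Emax convention: delta reported as count - proxy
    delta_emax, emax_flag = _delta(p_emax, c_emax, EMAX_FLAG_THRESHOLD)

    return FormatComparison(
        compound=compound,
        delta_log_ec50=delta_ec50,
        delta_emax=delta_emax,
        ec50_flag=ec50_flag,
        emax_flag=emax_flag,
    )
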