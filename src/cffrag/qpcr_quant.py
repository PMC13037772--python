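"""qPCR standard curves, absolute quantification, and the short-fragment index.

The short-fragment assay pair follows the multiplexed design used for canine
plasma: a short amplicon (LINE repeat, ~99 bp) amplifies nearly all cfDNA
molecules while a long amplicon (PECAM1 repeat, ~598 bp) amplifies only
fragments long enough to span it.  The short index

    short_index = (LINE_ng - PECAM_ng) / LINE_ng

is then the fraction of cfDNA amplifiable only by the short assay — a PCR
proxy for fragment shortness.  Any pre-quantified short/long pair (e.g. a
digital-PCR panel with 71 bp and 471 bp average amplicons) can be fed to
:func:`short_index` directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "QpcrQuantification",
    "fit_standard_curve",
    "quantify",
    "short_index",
    "concentration_per_ml",
    "quantify_samples",
    "read_qpcr_csv",
    "read_dilution_csv",
]


@dataclass(frozen=True)
class StandardCurve:
    """Linear calibration Cq = intercept + slope * log10(ng).

    ``slope`` is Cq per log10(ng) (negative for a working assay; the textbook
    perfect-efficiency value is -3.32), ``intercept`` the Cq at 1 ng, and
    ``efficiency`` = 10**(-1/slope) - 1 (1.0 means a perfect doubling per
    cycle).
    """

    slope: float
    intercept: float
    r_squared: float = 1.0
    valid: bool = True

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def cq(self, ng: float) -> float:
        """Noise-free Cq predicted for a template quantity in ng."""
        return self.intercept + self.slope * np.log10(ng)


@dataclass
class QpcrQuantification:
    sample_id: str
    line_ng: float
    pecam_ng: float
    short_index: float
    flags: set[str] = field(default_factory=set)


def fit_standard_curve(dilutions) -> StandardCurve:
    """Least-squares fit of Cq on log10(ng) from a dilution series.

    ``dilutions`` is an iterable of (ng, cq_replicates) pairs or a DataFrame
    with columns ``ng`` and ``cq``.  Replicate Cqs at each concentration are
    averaged before fitting.  Requires >= 3 distinct concentrations spanning
    >= 2 logs.  A fitted positive slope marks the curve invalid (template
    quantity and Cq must be anticorrelated).
    """
    if isinstance(dilutions, pd.DataFrame):
        grouped = dilutions.groupby("ng")["cq"].mean()
        ngs = grouped.index.to_numpy(dtype=float)
        cqs = grouped.to_numpy(dtype=float)
    else:
        pairs = [(float(ng), np.mean(np.atleast_1d(cq))) for ng, cq in dilutions]
        ngs = np.array([p[0] for p in pairs])
        cqs = np.array([p[1] for p in pairs])
    if np.unique(ngs).size < 3:
        raise ValueError("standard curve needs >= 3 distinct concentrations")
    if np.any(ngs <= 0):
        raise ValueError("concentrations must be positive")
    span = np.log10(ngs.max() / ngs.min())
    if span < 2:
        raise ValueError(f"dilution series spans {span:.2f} logs; >= 2 required")
    res = stats.linregress(np.log10(ngs), cqs)
    valid = res.slope < 0
    if not valid:
        import warnings

        warnings.warn("standard curve has non-negative slope; marked invalid", stacklevel=2)
    return StandardCurve(res.slope, res.intercept, res.rvalue**2, valid)


def quantify(cq: float | Sequence[float], curve: StandardCurve) -> float:
    """Invert a Cq (or mean of replicate Cqs) to an absolute quantity in ng."""
    if not curve.valid:
        raise ValueError("cannot quantify with an invalid standard curve")
    cq_mean = float(np.mean(np.atleast_1d(np.asarray(cq, dtype=float))))
    return 10.0 ** ((cq_mean - curve.intercept) / curve.slope)


def short_index(line_ng: float, pecam_ng: float) -> tuple[float, set[str]]:
    """Short-fragment index (LINE - PECAM)/LINE with quality flags.

    A negative value (long assay reading above the short one) is returned raw
    with a ``negative_index`` flag rather than clamped, so downstream
    statistics see the measurement as-is.
    """
    flags: set[str] = set()
    if line_ng <= 0:
        raise ValueError("no_amplification: short-assay quantity must be positive")
    value = (line_ng - pecam_ng) / line_ng
    if pecam_ng > line_ng:
        flags.add("negative_index")
    return value, flags


def concentration_per_ml(ng_total_eluate: float, plasma_ml: float) -> float:
    """Total eluate DNA (ng) expressed per mL of input plasma."""
    if plasma_ml <= 0:
        raise ValueError("plasma volume must be positive")
    if ng_total_eluate < 0:
        raise ValueError("DNA quantity cannot be negative")
    return ng_total_eluate / plasma_ml


def read_qpcr_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"sample_id", "assay", "replicate", "cq"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: qPCR CSV needs columns {sorted(need)}")
    return df


def read_dilution_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"ng", "cq"}.issubset(df.columns):
        raise ValueError(f"{path}: dilution CSV needs columns ['ng', 'cq']")
    return df


def quantify_samples(
    qpcr: pd.DataFrame,
    short_curve: StandardCurve,
    long_curve: StandardCurve | None = None,
) -> pd.DataFrame:
    """Per-sample quantities and short index from a replicate-level Cq table.

    ``qpcr`` columns: sample_id, assay in {short, long}, replicate, cq.
    Replicates are averaged on the Cq scale before inversion.  Samples whose
    short assay never amplified (all Cq missing) are flagged
    ``no_amplification`` and given a missing index.
    """
    long_curve = long_curve or short_curve
    rows = []
    for sample_id, sub in qpcr.groupby("sample_id", sort=True):
        out = {"sample_id": sample_id, "line_ng": np.nan, "pecam_ng": np.nan,
               "short_index": np.nan, "flags": ""}
        flags: set[str] = set()
        cq_s = sub.loc[sub["assay"] == "short", "cq"].dropna()
        cq_l = sub.loc[sub["assay"] == "long", "cq"].dropna()
        if len(cq_s) == 0:
            flags.add("no_amplification")
        else:
            out["line_ng"] = quantify(cq_s.to_numpy(), short_curve)
            # an exhausted long assay means no long template, not missing data
            out["pecam_ng"] = quantify(cq_l.to_numpy(), long_curve) if len(cq_l) else 0.0
            value, f = short_index(out["line_ng"], out["pecam_ng"])
            out["short_index"] = value
            flags |= f
        out["flags"] = ";".join(sorted(flags))
        rows.append(out)
    return pd.DataFrame(rows)
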