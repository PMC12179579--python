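"""Flow-cytometry genome traits: genome size, partial endoreplication, GC.

The measurements are peak positions (relative fluorescence) of nuclei
populations: the 2C peak and the series of endoreplicated peaks, under two
stains -- propidium iodide (PI, intercalating, base-neutral: the
quantitative stain) and DAPI (AT-preferential) -- plus an internal size
standard measured in the same run.

Partial endoreplication (PE) is the orchid-specific mode in which only a
fraction P of the genome is replicated in each endocycle, so the r-th
endoreplicated peak sits at

    F_r = F_0 * (1 + (2**r - 1) * P),        P in (0, 1]

with P = 1 recovering conventional whole-genome endoreplication (CE, exact
doubling).  Genome size follows from the sample/standard PI peak ratio; GC
content from the dye factor DF = DAPI/PI of the 2C peak under an
AT-preferential binding model with configurable binding length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "FcmRun",
    "TraitRecord",
    "CE_THRESHOLD",
    "genome_size",
    "replicated_fraction",
    "classify_endoreplication",
    "gc_content",
    "infer_fraction_gc",
    "derive_traits",
    "summarize_traits",
    "read_peak_table",
    "write_trait_table",
]

#: replicated-fraction threshold separating conventional (>=) from partial
#: endoreplication; inclusive on the CE side to absorb measurement error.
CE_THRESHOLD = 0.95

#: default effective binding length (consecutive AT base pairs) of DAPI.
DEFAULT_BINDING_LENGTH = 4


@dataclass(frozen=True)
class FcmRun:
    """Peak table of one accession (sample + internal standard, two stains)."""

    accession: str
    sample_peaks_pi: Tuple[float, ...]
    standard_peak_pi: float
    standard_2c_mbp: float
    sample_peaks_dapi: Optional[Tuple[float, ...]] = None
    standard_peak_dapi: Optional[float] = None
    standard_gc_pct: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "sample_peaks_pi", tuple(float(x) for x in self.sample_peaks_pi))
        if self.sample_peaks_dapi is not None:
            object.__setattr__(
                self, "sample_peaks_dapi", tuple(float(x) for x in self.sample_peaks_dapi)
            )
        peaks = self.sample_peaks_pi
        if not peaks:
            raise ValueError("no PI peaks")
        if any(p <= 0 for p in peaks):
            raise ValueError("fluorescence values must be positive")
        # the PE model bounds successive peak ratios in (1, 2]; allow
        # headroom above 2 for multiplicative measurement noise on CE runs
        # (the P fit clips to 1); ratios beyond 2.5 are not a plausible
        # endoreplication series under any noise level seen in practice
        for lo, hi in zip(peaks, peaks[1:]):
            if not (1.0 < hi / lo <= 2.5):
                raise ValueError(
                    "successive peak ratio %.3f outside (1, 2]: peaks must be an "
                    "increasing endoreplication series" % (hi / lo)
                )
        if self.standard_peak_pi <= 0:
            raise ValueError("standard PI peak must be positive")


@dataclass
class TraitRecord:
    accession: str
    gs_2c_mbp: float
    gs_1c_mbp: float
    p: Optional[float] = None
    endo_type: Optional[str] = None  # "CE" | "PE"
    gc_pct: Optional[float] = None
    replicated_gs_mbp: Optional[float] = None


def genome_size(run: FcmRun) -> Tuple[float, float]:
    """(2C, 1C) genome size in Mbp from the sample/standard PI peak ratio."""
    if run.standard_2c_mbp is None or run.standard_2c_mbp <= 0:
        raise ValueError("missing or non-positive standard genome size")
    gs_2c = run.sample_peaks_pi[0] / run.standard_peak_pi * run.standard_2c_mbp
    return gs_2c, gs_2c / 2.0


def replicated_fraction(peaks) -> float:
    """Least-squares fit of the PE peak model over all endocycle rounds.

    ``peaks`` is one fluorescence series (2C, 4C', 8C', ...) or a sequence
    of such series (e.g. the PI and DAPI series of the same accession);
    with several series a single shared P is fitted with one free baseline
    per series.

    The fit minimizes squared residuals of log peak positions: peak noise
    is multiplicative, so log residuals are the homoskedastic scale (and
    the fit is maximum likelihood under lognormal noise).  For fixed P the
    optimal baseline is closed-form, leaving a one-dimensional bounded
    minimization over P in (0, 1]; the result is clipped to (0, 1].
    """
    first = next(iter(peaks))
    series = [peaks] if np.ndim(first) == 0 else list(peaks)
    logs = []
    for s in series:
        y = np.asarray(s, dtype=float)
        if y.size < 2:
            raise ValueError("need at least two peaks to estimate P")
        if np.any(y <= 0):
            raise ValueError("fluorescence values must be positive")
        logs.append(np.log(y))

    def sse(p):
        total = 0.0
        for ly in logs:
            lm = np.log(1.0 + (2.0 ** np.arange(ly.size) - 1.0) * p)
            resid = ly - lm
            resid = resid - resid.mean()  # profile out the series baseline
            total += float(resid @ resid)
        return total

    res = minimize_scalar(sse, bounds=(1e-9, 1.0), method="bounded",
                          options={"xatol": 1e-10})
    p_hat = float(res.x)
    # boundary polish: the bounded optimizer can stop a hair inside 1.0
    if sse(1.0) <= res.fun + 1e-12:
        p_hat = 1.0
    return min(max(p_hat, 1e-9), 1.0)


def classify_endoreplication(p: float) -> str:
    """'CE' iff P >= the 95% threshold (inclusive), else 'PE'."""
    if not (0.0 < p <= 1.0 + 1e-12):
        raise ValueError("P must be in (0, 1]")
    return "CE" if p >= CE_THRESHOLD else "PE"


def gc_content(run: FcmRun, binding_length: int = DEFAULT_BINDING_LENGTH) -> float:
    """GC %% from the 2C dye factor under the AT-binding model.

    DAPI fluorescence is taken proportional to (AT fraction)**n with n the
    effective binding length, so with DF = DAPI/PI at 2C:

        AT_sample = AT_standard * (DF_sample / DF_standard) ** (1/n)
        GC_sample = 100 - AT_sample
    """
    if run.sample_peaks_dapi is None or run.standard_peak_dapi is None:
        raise ValueError("both stains required for GC estimation")
    if run.standard_gc_pct is None:
        raise ValueError("standard GC content required")
    if run.sample_peaks_dapi[0] <= 0 or run.standard_peak_dapi <= 0:
        raise ValueError("fluorescence values must be positive")
    df_sample = run.sample_peaks_dapi[0] / run.sample_peaks_pi[0]
    df_standard = run.standard_peak_dapi / run.standard_peak_pi
    at_standard = 100.0 - run.standard_gc_pct
    at_sample = at_standard * (df_sample / df_standard) ** (1.0 / binding_length)
    return 100.0 - at_sample


def peak_gc_series(run: FcmRun, binding_length: int = DEFAULT_BINDING_LENGTH) -> List[float]:
    """GC %% per peak (2C, first endocycle, ...) from per-peak dye factors."""
    if run.sample_peaks_dapi is None:
        raise ValueError("both stains required for GC estimation")
    if len(run.sample_peaks_dapi) != len(run.sample_peaks_pi):
        raise ValueError("stain peak series lengths differ")
    out = []
    df_standard = run.standard_peak_dapi / run.standard_peak_pi
    at_standard = 100.0 - run.standard_gc_pct
    for dapi, pi in zip(run.sample_peaks_dapi, run.sample_peaks_pi):
        df = dapi / pi
        out.append(100.0 - at_standard * (df / df_standard) ** (1.0 / binding_length))
    return out


def infer_fraction_gc(gc_0: float, gc_1: float, p: float) -> float:
    """GC %% of the replicated genome fraction by mass balance.

    A nucleus after one endocycle carries the full genome plus the
    replicated fraction P, so GC_1 * (1 + P) = GC_0 + P * GC_rep, giving

        GC_rep = (GC_1 * (1 + P) - GC_0) / P.

    Values outside (0, 100) are returned but flagged with a warning: they
    indicate a violation of the two-component mixing model.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError("P must be in (0, 1]")
    gc_rep = (gc_1 * (1.0 + p) - gc_0) / p
    if not (0.0 < gc_rep < 100.0):
        warnings.warn(
            "inferred replicated-fraction GC %.2f%% outside (0, 100): "
            "mixing-model violation" % gc_rep
        )
    return gc_rep


def derive_traits(
    run: FcmRun,
    binding_length: int = DEFAULT_BINDING_LENGTH,
    use_both_stains: bool = True,
) -> TraitRecord:
    """Full per-accession derivation: GS, P, CE/PE, GC, replicated GS.

    With ``use_both_stains`` (default) the replicated fraction is fitted
    jointly on the PI and DAPI peak series (both display the same
    endocycle spacing), roughly halving its variance; set it False when a
    strong GC shift of the replicated fraction is suspected to distort the
    DAPI spacing.
    """
    gs2c, gs1c = genome_size(run)
    rec = TraitRecord(accession=run.accession, gs_2c_mbp=gs2c, gs_1c_mbp=gs1c)
    if len(run.sample_peaks_pi) >= 2:
        series = [run.sample_peaks_pi]
        if (
            use_both_stains
            and run.sample_peaks_dapi is not None
            and len(run.sample_peaks_dapi) == len(run.sample_peaks_pi)
        ):
            series.append(run.sample_peaks_dapi)
        rec.p = replicated_fraction(series)
        rec.endo_type = classify_endoreplication(rec.p)
        rec.replicated_gs_mbp = rec.p * gs1c
    if run.sample_peaks_dapi is not None and run.standard_gc_pct is not None:
        rec.gc_pct = gc_content(run, binding_length=binding_length)
    return rec


def summarize_traits(
    records: Sequence[TraitRecord],
    value: str = "gs_1c_mbp",
    by: Optional[str] = None,
) -> pd.DataFrame:
    """Range / fold statistics of one trait, optionally grouped.

    Columns: n, min, max, fold (max/min), range (max - min).
    """
    if not records:
        raise ValueError("no records")
    rows = []
    for r in records:
        v = getattr(r, value)
        if v is None:
            continue
        rows.append({"accession": r.accession, "value": float(v),
                     "group": getattr(r, by) if by else "all"})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no records carry trait %r" % value)

    def agg(g):
        return pd.Series({
            "n": len(g),
            "min": g["value"].min(),
            "max": g["value"].max(),
            "fold": g["value"].max() / g["value"].min(),
            "range": g["value"].max() - g["value"].min(),
        })

    out = df.groupby("group", sort=True).apply(agg, include_groups=False)
    out["n"] = out["n"].astype(int)
    return out


# ---------------------------------------------------------------------------
# TSV interface (one row per accession)

_PEAK_COLUMNS = [
    "accession", "pi_peaks", "dapi_peaks", "standard_pi", "standard_dapi",
    "standard_2c_mbp", "standard_gc_pct",
]


def read_peak_table(path) -> List[FcmRun]:
    """Read a TSV peak table; peak series are comma-separated in one cell."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("accession", "pi_peaks", "standard_pi", "standard_2c_mbp")
               if c not in df.columns]
    if missing:
        raise ValueError("peak table missing columns: %s" % ", ".join(missing))
    runs = []
    for _, row in df.iterrows():
        dapi = row.get("dapi_peaks")
        runs.append(FcmRun(
            accession=row["accession"],
            sample_peaks_pi=[float(x) for x in str(row["pi_peaks"]).split(",")],
            sample_peaks_dapi=(
                [float(x) for x in str(dapi).split(",")]
                if isinstance(dapi, str) and dapi else None
            ),
            standard_peak_pi=float(row["standard_pi"]),
            standard_peak_dapi=(
                float(row["standard_dapi"]) if isinstance(row.get("standard_dapi"), str) else None
            ),
            standard_2c_mbp=float(row["standard_2c_mbp"]),
            standard_gc_pct=(
                float(row["standard_gc_pct"]) if isinstance(row.get("standard_gc_pct"), str) else None
            ),
        ))
    return runs


def write_trait_table(records: Sequence[TraitRecord], path) -> None:
    df = pd.DataFrame([{
        "accession": r.accession,
        "gs_1c_mbp": r.gs_1c_mbp,
        "gs_2c_mbp": r.gs_2c_mbp,
        "gc_pct": r.gc_pct,
        "endo_type": r.endo_type,
        "p": r.p,
        "replicated_gs_mbp": r.replicated_gs_mbp,
    } for r in records])
    df.to_csv(path, sep="\t", index=False)
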