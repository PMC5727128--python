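"""Two-species comparisons of absolute and relative brain measurements.

Designed for very small samples (n = 3 per species is typical of
whole-brain histology): plain two-sample t-tests on absolute volumes and on
per-specimen proportions (region / whole brain, plus olfactory bulb /
telencephalon), and headline mean-ratio summaries. The pooled-variance
(Student) t is the default; Welch is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = ["GroupComparison", "pooled_t_from_summary", "relative_measures",
           "compare_specimens", "ratio_report", "bundled_vulture_summaries"]


@dataclass
class GroupComparison:
    measure: str
    mode: str  # absolute | proportion-of-brain | proportion-of-telencephalon
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    t: float
    df: float
    p: float

    def to_row(self) -> dict:
        return self.__dict__.copy()


def pooled_t_from_summary(m1: float, sd1: float, n1: int,
                          m2: float, sd2: float, n2: int, *,
                          measure: str = "", mode: str = "absolute",
                          welch: bool = False) -> GroupComparison:
    """Two-sample t-test from group summary statistics.

    Pooled-variance (Student) by default, df = n1 + n2 − 2; set ``welch``
    for the unequal-variance test with Satterthwaite df. If both SDs are
    zero the statistic degenerates: equal means give t = 0, p = 1;
    different means give an infinite t, with p reported as the smallest
    positive float (a numeric underflow bound, not a literal zero).
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("standard deviations must be >= 0")
    if sd1 == 0 and sd2 == 0:
        if m1 == m2:
            df = float(n1 + n2 - 2)
            return GroupComparison(measure, mode, m1, sd1, n1, m2, sd2, n2,
                                   t=0.0, df=df, p=1.0)
        df = float(n1 + n2 - 2)
        t = np.inf if m1 > m2 else -np.inf
        return GroupComparison(measure, mode, m1, sd1, n1, m2, sd2, n2,
                               t=t, df=df, p=float(np.finfo(float).tiny))
    if welch:
        t, p = stats.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2,
                                          equal_var=False)[:2]
        v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    else:
        df = float(n1 + n2 - 2)
        sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * stats.t.sf(abs(t), df)
    return GroupComparison(measure, mode, m1, sd1, n1, m2, sd2, n2,
                           t=float(t), df=float(df), p=float(p))


def relative_measures(specimens: pd.DataFrame, *,
                      regions: list[str] | None = None,
                      brain_col: str = "whole_brain",
                      telencephalon_col: str = "telencephalon",
                      ob_col: str = "olfactory_bulb",
                      exclude: tuple = ("mitral_cells",)) -> pd.DataFrame:
    """Per-specimen proportions of each region against whole-brain volume,
    plus olfactory bulb against telencephalon.

    `specimens` is wide: one row per specimen with a ``species`` column and
    one numeric column per measure. Count-valued measures (cell numbers)
    are not proportions of a volume and are excluded by default.
    """
    if "species" not in specimens.columns:
        raise ValidationError("specimens table needs a 'species' column")
    if (specimens[brain_col] <= 0).any():
        raise ValidationError("whole-brain volume must be positive")
    if regions is None:
        regions = [c for c in specimens.columns
                   if c not in ("species", "specimen", brain_col)
                   and c not in exclude
                   and pd.api.types.is_numeric_dtype(specimens[c])]
    out = specimens[[c for c in ("specimen", "species")
                     if c in specimens.columns]].copy()
    for region in regions:
        if (specimens[region] > specimens[brain_col]).any():
            raise ValidationError(
                f"region {region!r} exceeds whole-brain volume for some "
                "specimen")
        out[f"{region}_of_brain"] = specimens[region] / specimens[brain_col]
    if telencephalon_col in specimens.columns and ob_col in specimens.columns:
        out[f"{ob_col}_of_telencephalon"] = (
            specimens[ob_col] / specimens[telencephalon_col])
    return out


def compare_specimens(specimens: pd.DataFrame, species_a: str,
                      species_b: str, *, mode: str = "absolute",
                      welch: bool = False) -> pd.DataFrame:
    """t-tests for every numeric measure between two species, from raw
    per-specimen values (absolute mode) or precomputed proportions."""
    cols = [c for c in specimens.columns
            if c not in ("species", "specimen")
            and pd.api.types.is_numeric_dtype(specimens[c])]
    a = specimens[specimens["species"] == species_a]
    b = specimens[specimens["species"] == species_b]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need >= 2 specimens per species")
    rows = []
    for c in cols:
        g = pooled_t_from_summary(
            a[c].mean(), a[c].std(ddof=1), len(a),
            b[c].mean(), b[c].std(ddof=1), len(b),
            measure=c, mode=mode, welch=welch)
        rows.append(g.to_row())
    return pd.DataFrame(rows)


def ratio_report(summaries: pd.DataFrame, *, focal: str, reference: str,
                 brain_measure: str = "whole_brain") -> dict:
    """Headline mean ratios (focal / reference) per measure and the percent
    by which the focal species' brain is smaller than the reference's.

    `summaries` has columns: measure, species, mean (sd/n optional).
    """
    piv = summaries.pivot(index="measure", columns="species", values="mean")
    for sp in (focal, reference):
        if sp not in piv.columns:
            raise ValidationError(f"species {sp!r} missing from summaries")
    if (piv[reference] == 0).any():
        raise ValidationError("reference mean of zero: ratio undefined")
    ratios = (piv[focal] / piv[reference]).to_dict()
    out = {"focal": focal, "reference": reference, "ratios": ratios}
    if brain_measure in piv.index:
        ref_brain = piv.loc[brain_measure, reference]
        out["brain_percent_difference"] = float(
            (ref_brain - piv.loc[brain_measure, focal]) / ref_brain * 100.0)
    return out


def bundled_vulture_summaries() -> pd.DataFrame:
    """Reported brain measurements of turkey and black vultures: mean, SD
    and n per species for seven measures (volumes in mm³, mitral cells as
    counts). Columns: measure, species, mean, sd, n."""
    ref = resources.files("phyloallometry.data") / "vulture_region_summaries.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
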