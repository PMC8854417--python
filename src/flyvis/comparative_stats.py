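"""Non-phylogenetic group statistics on species means.

Each species contributes one point (its trait mean): pooled-variance
two-sample t-tests between the SAT and NON-SAT groups, SAT/NON-SAT ratio
summaries, ordinary least squares, and Pearson correlations between
size-relative (trait / head width x 100) visual and antennal traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_fixtures import NON_SAT, SAT, RegimeAssignment, SpeciesTraitTable
from .morphometrics import relative_trait


@dataclass
class GroupContrast:
    """SAT vs NON-SAT contrast of one trait across species means."""

    trait: str
    mean_SAT: float
    se_SAT: float | None
    n_SAT: int
    mean_NONSAT: float
    se_NONSAT: float | None
    n_NONSAT: int
    ratio: float
    ratio_direction: str  # 'SAT/NON_SAT' or 'NON_SAT/SAT', whichever >= 1
    t: float
    df: int
    p: float

    def to_dict(self) -> dict:
        return {
            k: (None if isinstance(v, float) and np.isnan(v) else v)
            for k, v in self.__dict__.items()
        }


def pooled_t_test(a, b, welch: bool = False) -> tuple[float, int, float]:
    """Two-sample t-test on species means (equal-variance by default).

    Returns (t, df, two-sided p) with df = n1 + n2 - 2 for the pooled test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = res.df if welch else len(a) + len(b) - 2
    return float(res.statistic), float(df) if welch else int(df), float(res.pvalue)


def group_summary(
    traits: SpeciesTraitTable, regimes: RegimeAssignment, trait: str
) -> GroupContrast:
    """Unweighted group means, SEs and the >= 1 direction-flagged ratio."""
    regimes.check_covers(traits.species)
    m = traits.mean(trait).astype(float)
    sat = m[[s for s in traits.species if regimes[s] == SAT]].dropna()
    non = m[[s for s in traits.species if regimes[s] == NON_SAT]].dropna()
    if len(sat) == 0 or len(non) == 0:
        raise ValueError(f"trait {trait!r}: empty regime group")
    ratio = sat.mean() / non.mean()
    direction = "SAT/NON_SAT"
    if ratio < 1:
        ratio, direction = 1.0 / ratio, "NON_SAT/SAT"
    if len(sat) >= 2 and len(non) >= 2:
        t, df, p = pooled_t_test(sat, non)
    else:
        t, df, p = np.nan, len(sat) + len(non) - 2, np.nan
    return GroupContrast(
        trait=trait,
        mean_SAT=float(sat.mean()),
        se_SAT=float(sat.sem()) if len(sat) > 1 else None,
        n_SAT=len(sat),
        mean_NONSAT=float(non.mean()),
        se_NONSAT=float(non.sem()) if len(non) > 1 else None,
        n_NONSAT=len(non),
        ratio=float(ratio),
        ratio_direction=direction,
        t=float(t),
        df=df,
        p=float(p),
    )


def ols_regression(x, y) -> tuple[float, float, float]:
    """Simple least squares: returns (slope, intercept, R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def relative_correlations(
    traits: SpeciesTraitTable,
    eye_traits: list[str],
    antennal_traits: list[str],
    log_transform: bool = False,
) -> pd.DataFrame:
    """Pearson r and p for every (eye, antennal) size-relative trait pair.

    Traits are divided by head width (x 100) species-wise before
    correlating; optionally natural-log transformed afterwards.
    """
    hw = traits.mean("H_width").astype(float)
    rel = {}
    for tr in list(eye_traits) + list(antennal_traits):
        rel[tr] = relative_trait(
            traits.mean(tr).astype(float).to_numpy(), hw.to_numpy()
        )
    complete = np.all(
        [np.isfinite(rel[tr]) for tr in rel], axis=0
    )
    if complete.sum() < 3:
        raise ValueError("fewer than 3 species with complete trait data")
    rows = []
    for eye in eye_traits:
        for ant in antennal_traits:
            a, b = rel[eye][complete], rel[ant][complete]
            if log_transform:
                a, b = np.log(a), np.log(b)
            r, p = stats.pearsonr(a, b)
            rows.append({"eye_trait": eye, "antennal_trait": ant, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)
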