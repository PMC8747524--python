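"""Single-marker association statistics.

Marker genotypes across cultivars are coded additively (hh = 2 donor
alleles, hl = 1, ll = 0; failed-PCR calls excluded; dominant calls make
the marker not estimable), and marker-trait association is measured by
ordinary least squares of the cultivar trait means on the coded
genotypes (R^2 = squared Pearson correlation).  One-way ANOVA and
Duncan's multiple range test support cultivar-level comparisons; both
also run from summary statistics (mean, sd, n per group) when the
replicate values themselves are unavailable.

Duncan's test compares ranked group means against least significant
ranges LSR_r = q(1 - alpha_r; r, df_e) * sqrt(MSE / n), with the
protection level alpha_r = 1 - (1 - alpha)^(r - 1) for means that are
r ranks apart, q being the studentized range quantile.
"""

from __future__ import annotations

import functools
import logging
import string
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GENOTYPE_CODES = {"hh": 2, "hl": 1, "ll": 0}
VALID_CODES = set(GENOTYPE_CODES) | {"d", "m"}


class NotEstimableError(ValueError):
    """Marker cannot be scored (dominant calls or <2 genotype classes)."""


@dataclass
class AssociationResult:
    marker: str
    n: int
    slope: float | None
    intercept: float | None
    r2: float | None
    p_regression: float | None
    anova_f: float | None
    anova_p: float | None
    status: str  # OK | NOT_ESTIMABLE
    reason: str = ""
    duncan_letters: dict[str, str] | None = None


def load_phenotypes(path: str | Path | None = None) -> pd.DataFrame:
    """Cultivar trait table (entry, cultivar, mean, sd, n).

    Without a path, the packaged trans-lycopene table of the 20
    cultivars (donor, recurrents, NILs, breeding lines and F1s) loads.
    """
    if path is None:
        ref = resources.files("nilscan.data") / "lycopene_phenotypes.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    if (df["n"] < 1).any() or (df["sd"] < 0).any():
        raise ValueError("phenotype table needs n >= 1 and sd >= 0")
    return df


def load_marker_genotypes(path: str | Path | None = None) -> pd.DataFrame:
    """Marker x cultivar genotype-code table (codes hh/hl/ll/d/m).

    Columns are entry numbers matching the phenotype table; an optional
    ``r2_printed`` column carries published values for comparison.
    Without a path, the packaged 26-marker CAPS genotyping table loads.
    """
    if path is None:
        ref = resources.files("nilscan.data") / "caps_marker_genotypes.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    code_cols = [c for c in df.columns if c not in ("marker", "r2_printed")]
    for col in code_cols:
        bad = set(df[col]) - VALID_CODES
        if bad:
            raise ValueError(f"unknown genotype codes {sorted(bad)} in column {col}")
    return df


def code_genotypes(codes: Mapping[str, str], marker: str = "?") -> dict[str, int]:
    """Additive coding hh->2, hl->1, ll->0; m excluded; d not estimable."""
    out: dict[str, int] = {}
    for cultivar, code in codes.items():
        if code not in VALID_CODES:
            raise ValueError(
                f"unknown genotype code {code!r} for cultivar {cultivar} "
                f"at marker {marker}"
            )
        if code == "m":  # failed PCR: drop the cultivar
            continue
        if code == "d":
            raise NotEstimableError(
                f"marker {marker}: dominant code for cultivar {cultivar}"
            )
        out[cultivar] = GENOTYPE_CODES[code]
    return out


def single_marker_r2(
    x: Sequence[float], y: Sequence[float], marker: str = "?"
) -> AssociationResult:
    """OLS of trait on coded genotype; R^2 and two-sided slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be the same length")
    if x.size < 3 or np.unique(x).size < 2:
        return AssociationResult(
            marker=marker, n=int(x.size), slope=None, intercept=None,
            r2=None, p_regression=None, anova_f=None, anova_p=None,
            status="NOT_ESTIMABLE", reason="<3 points or constant genotype",
        )
    lr = stats.linregress(x, y)
    groups = {v: y[x == v] for v in np.unique(x)}
    f = p = None
    if all(len(g) >= 1 for g in groups.values()) and sum(
        len(g) for g in groups.values()
    ) - len(groups) >= 1 and any(len(g) > 1 for g in groups.values()):
        f, p = one_way_anova(groups)
    return AssociationResult(
        marker=marker, n=int(x.size), slope=float(lr.slope),
        intercept=float(lr.intercept), r2=float(lr.rvalue**2),
        p_regression=float(lr.pvalue), anova_f=f, anova_p=p, status="OK",
    )


def one_way_anova(groups: Mapping[object, Sequence[float]]) -> tuple[float, float]:
    """Between/within F decomposition with its p-value."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = []
    for label, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {label!r} is empty")
        arrays.append(arr)
    n_total = sum(a.size for a in arrays)
    if n_total - len(arrays) < 1:
        raise ValueError("no residual degrees of freedom")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def anova_from_summary(
    means: Sequence[float], sds: Sequence[float], ns: Sequence[int]
) -> tuple[float, float]:
    """One-way ANOVA from per-group mean, sd and n.

    The between and within sums of squares are exactly recoverable
    from summary statistics, so the F test equals the one computed
    from the raw replicate values.
    """
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    ns = np.asarray(ns, int)
    if np.any(ns < 2):
        raise ValueError("summary ANOVA needs n >= 2 per group")
    k = means.size
    n_total = int(ns.sum())
    grand = float(np.sum(ns * means) / n_total)
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(np.sum((ns - 1) * sds**2))
    df_b, df_w = k - 1, n_total - k
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return f, p


def _duncan_letters_from_ranges(
    labels: list[object],
    means: np.ndarray,
    lsr: np.ndarray,
) -> dict[object, str]:
    """Assign letters given means sorted descending and LSR per span r.

    ``lsr[r-2]`` is the least significant range for means r ranks
    apart.  A pair is declared non-significant when its difference is
    below the LSR of its span or when it lies inside a larger span
    already declared non-significant (Duncan's containment rule).
    Letters mark the maximal homogeneous runs.
    """
    k = len(labels)
    nonsig = np.zeros((k, k), dtype=bool)
    for span in range(k, 1, -1):  # largest spans first
        for i in range(0, k - span + 1):
            j = i + span - 1
            if nonsig[i, j]:
                continue
            if means[i] - means[j] <= lsr[span - 2]:
                nonsig[i:j + 1, i:j + 1] = True
    np.fill_diagonal(nonsig, True)
    # nonsig is only ever set by whole-block fills, so nonsig[i, j]
    # means the entire run [i..j] is homogeneous
    runs: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and nonsig[i, j + 1]:
            j += 1
        runs.append((i, j))
    maximal = [
        r for r in runs
        if not any(s != r and s[0] <= r[0] and r[1] <= s[1] for s in runs)
    ]
    letter_sets: dict[object, list[str]] = {lab: [] for lab in labels}
    alphabet = string.ascii_lowercase
    # letter 'a' goes to the lowest-mean run, as trait tables print them
    for idx, (i, j) in enumerate(sorted(maximal, key=lambda r: -r[0])):
        ch = alphabet[idx % 26] * (idx // 26 + 1)
        for t in range(i, j + 1):
            letter_sets[labels[t]].append(ch)
    return {lab: "".join(sorted(chs)) for lab, chs in letter_sets.items()}


def duncan_mrt(
    groups: Mapping[object, Sequence[float]],
    alpha: float = 0.05,
) -> dict[object, str]:
    """Duncan's multiple range test letters from replicate values.

    Unbalanced groups use the harmonic mean of the group sizes in the
    range standard error (a warning is logged).
    """
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("every group needs >= 2 replicates")
    ns = np.array([a.size for a in arrays.values()])
    means = np.array([a.mean() for a in arrays.values()])
    sds = np.array([a.std(ddof=1) for a in arrays.values()])
    if len(set(ns.tolist())) > 1:
        logger.warning("unbalanced groups: using harmonic mean n in Duncan ranges")
    return duncan_mrt_from_summary(
        dict(zip(arrays.keys(), means)), dict(zip(arrays.keys(), sds)),
        dict(zip(arrays.keys(), ns.tolist())), alpha=alpha,
    )


@functools.lru_cache(maxsize=4096)
def _duncan_q(alpha: float, span: int, df_error: int) -> float:
    """Studentized-range quantile at Duncan's protection level (cached:
    the quantile is expensive and depends only on alpha, span and df)."""
    protection = 1.0 - (1.0 - alpha) ** (span - 1)
    return float(stats.studentized_range.ppf(1.0 - protection, span, df_error))


def duncan_mrt_from_summary(
    means: Mapping[object, float],
    sds: Mapping[object, float],
    ns: Mapping[object, int],
    alpha: float = 0.05,
) -> dict[object, str]:
    """Duncan letters from per-group summary statistics."""
    labels = list(means)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two groups")
    n_arr = np.array([ns[l] for l in labels], dtype=float)
    df_error = int(n_arr.sum()) - k
    if df_error < 1:
        raise ValueError("no error degrees of freedom")
    mse = float(
        np.sum((n_arr - 1) * np.array([sds[l] for l in labels]) ** 2) / df_error
    )
    n_h = k / np.sum(1.0 / n_arr)  # harmonic mean group size
    se = np.sqrt(mse / n_h)
    lsr = np.array(
        [_duncan_q(alpha, span, df_error) for span in range(2, k + 1)]
    ) * se
    order = sorted(labels, key=lambda l: means[l], reverse=True)
    m_sorted = np.array([means[l] for l in order])
    return _duncan_letters_from_ranges(order, m_sorted, lsr)


def analyze_markers(
    phenotypes: pd.DataFrame,
    markers: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every marker against the cultivar trait means.

    Returns one row per marker: n used, slope, R^2, regression p,
    genotype-class ANOVA F/p and status (markers with dominant codes
    are NOT_ESTIMABLE, mirroring how published tables print "-").
    """
    pheno = phenotypes.set_index(phenotypes["en"].astype(str))["mean"]
    code_cols = [c for c in markers.columns if c not in ("marker", "r2_printed")]
    rows = []
    for _, mrow in markers.iterrows():
        marker = mrow["marker"]
        codes = {c: mrow[c] for c in code_cols}
        try:
            coded = code_genotypes(codes, marker=marker)
        except NotEstimableError as exc:
            rows.append(
                AssociationResult(
                    marker=marker, n=0, slope=None, intercept=None, r2=None,
                    p_regression=None, anova_f=None, anova_p=None,
                    status="NOT_ESTIMABLE", reason=str(exc),
                )
            )
            continue
        x = [coded[c] for c in coded]
        y = [float(pheno[c]) for c in coded]
        rows.append(single_marker_r2(x, y, marker=marker))
    out = pd.DataFrame(
        [
            {
                "marker": r.marker, "n": r.n, "slope": r.slope, "r2": r.r2,
                "p_regression": r.p_regression, "anova_f": r.anova_f,
                "anova_p": r.anova_p, "status": r.status, "reason": r.reason,
            }
            for r in rows
        ]
    )
    if "r2_printed" in markers.columns:
        out["r2_printed"] = markers["r2_printed"].to_numpy()
    return out
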