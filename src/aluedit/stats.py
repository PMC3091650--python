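"""Frequency, enrichment and contingency statistics for editing-site tables.

All functions operate on a "sites" DataFrame carrying one row per adenosine
with at least an ``is_edited`` label (E1 = True, E0 = False) and the
structural/sequence context columns produced by
:func:`aluedit.structure.contexts_to_frame` (``kind``, ``strand_len``,
``ce_pos``, ``asymmetry``, ``op_nuc``, ``up1``..``up30``, ``dn1``..``dn30``).

Conventions:

* proportions get Wilson score 95% confidence intervals;
* enrichment factor of a context = editing frequency among sites with that
  context divided by the mean editing frequency over all sites eligible for
  the table (the stratum baseline), so the site-share-weighted mean of the
  enrichment factors is 1 by construction;
* chi-square tests are Pearson without continuity correction.
"""

from __future__ import annotations

import importlib.resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

BASES = ("A", "C", "G", "T")


def wilson_interval(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if n == 0:
        return (float("nan"), float("nan"))
    lo, hi = proportion_confint(k, n, alpha=1 - confidence, method="wilson")
    lo = 0.0 if k == 0 else max(float(lo), 0.0)
    hi = 1.0 if k == n else min(float(hi), 1.0)
    return lo, hi


def frequency_by(
    sites: pd.DataFrame, keys: str | Sequence[str], label_col: str = "is_edited"
) -> pd.DataFrame:
    """Editing frequency per group with Wilson 95% CIs.

    ``keys`` may be any context column(s): ``kind``, ``strand_len``,
    ``ce_pos``, ``asymmetry``, ``helix_flank``, ...
    """
    if isinstance(keys, str):
        keys = [keys]
    grouped = sites.groupby(list(keys), observed=True, dropna=True)
    rows = []
    for key, g in grouped:
        n = len(g)
        k = int(g[label_col].sum())
        lo, hi = wilson_interval(k, n)
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update(n_sites=n, n_edited=k, freq=k / n, ci_low=lo, ci_high=hi)
        rows.append(row)
    return pd.DataFrame(rows).sort_values(list(keys)).reset_index(drop=True)


def asymmetry_profile(
    sites: pd.DataFrame, strand_lengths: Iterable[int] = (1, 2, 3, 4),
    label_col: str = "is_edited",
) -> pd.DataFrame:
    """Normalised editing frequency vs interior-loop asymmetry.

    For each own-strand length L in ``strand_lengths`` and each asymmetry a
    (opposite length minus own length), the editing frequency of (L, a) sites
    is divided by the mean frequency of all length-L interior sites, so a
    value of 1 means "no asymmetry effect".
    """
    interior = sites[(sites["kind"] == "interior") & sites["strand_len"].isin(strand_lengths)]
    rows = []
    for length, g_len in interior.groupby("strand_len"):
        base = g_len[label_col].mean()
        for asym, g in g_len.groupby("asymmetry"):
            n = len(g)
            k = int(g[label_col].sum())
            lo, hi = wilson_interval(k, n)
            rows.append(
                {
                    "strand_len": int(length),
                    "asymmetry": int(asym),
                    "n_sites": n,
                    "n_edited": k,
                    "freq": k / n,
                    "normalized_freq": (k / n) / base if base > 0 else np.nan,
                    "ci_low": lo / base if base > 0 else np.nan,
                    "ci_high": hi / base if base > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


_FEATURE_COLUMNS = {
    "up1": ("up1",),
    "dn1": ("dn1",),
    "op_nuc": ("op_nuc",),
    "joint_up_dn": ("up1", "dn1"),
    "joint_up_dn_op": ("up1", "dn1", "op_nuc"),
}


def _context_string(feature: str, values: tuple) -> str:
    if feature == "joint_up_dn":
        return f"{values[0]},{values[1]}"
    if feature == "joint_up_dn_op":
        return f"{values[0]},{values[1]}:{values[2]}"
    return str(values[0])


def enrichment_factors(
    sites: pd.DataFrame,
    feature: str,
    stratum: str | None = None,
    min_support: int = 50,
    label_col: str = "is_edited",
) -> pd.DataFrame:
    """Editing enrichment factors for a sequence-context feature.

    ``feature`` is one of ``up1``, ``dn1``, ``op_nuc``, ``joint_up_dn``,
    ``joint_up_dn_op``.  ``stratum`` restricts to one substructure kind
    (typically ``helix`` or ``interior``).  The eligible set consists of
    stratum sites whose feature columns are all defined nucleotides; the
    shared baseline is the mean editing frequency over that set and is
    reported in the ``baseline`` column of every row.  Contexts with fewer
    than ``min_support`` sites are flagged ``low_support``.
    """
    if feature not in _FEATURE_COLUMNS:
        raise ValueError(f"unknown feature {feature!r}; one of {sorted(_FEATURE_COLUMNS)}")
    cols = _FEATURE_COLUMNS[feature]
    sub = sites if stratum is None else sites[sites["kind"] == stratum]
    mask = np.ones(len(sub), dtype=bool)
    for c in cols:
        mask &= sub[c].isin(BASES).to_numpy()
    eligible = sub[mask]
    if eligible.empty:
        return pd.DataFrame(
            columns=["context", *cols, "n_sites", "n_edited", "freq", "enrichment",
                     "baseline", "low_support"]
        )
    baseline = eligible[label_col].mean()
    rows = []
    for key, g in eligible.groupby(list(cols)):
        key = key if isinstance(key, tuple) else (key,)
        n = len(g)
        k = int(g[label_col].sum())
        row = {"context": _context_string(feature, key)}
        row.update(dict(zip(cols, key)))
        row.update(
            n_sites=n,
            n_edited=k,
            freq=k / n,
            enrichment=(k / n) / baseline if baseline > 0 else np.nan,
            baseline=baseline,
            low_support=n < min_support,
        )
        rows.append(row)
    return pd.DataFrame(rows).sort_values("context").reset_index(drop=True)


def neighbor_chi2(
    sites: pd.DataFrame,
    offsets: Iterable[int] | None = None,
    stratum: str | None = None,
    label_col: str = "is_edited",
) -> pd.DataFrame:
    """Pearson chi-square comparison of neighbour nucleotide composition.

    For each offset (negative = upstream, positive = downstream, never 0) the
    2x4 contingency table of (E1, E0) x (A, C, G, T) is formed from sites
    whose neighbour at that offset lies within the structure record, and the
    Pearson chi-square statistic (df = 3, no continuity correction) is
    computed together with the per-class nucleotide fractions.  Tables with
    any expected cell below 5 are flagged.
    """
    if offsets is None:
        offsets = [o for o in range(-30, 31) if o != 0]
    sub = sites if stratum is None else sites[sites["kind"] == stratum]
    rows = []
    for off in offsets:
        col = f"up{-off}" if off < 0 else f"dn{off}"
        if col not in sub.columns:
            raise KeyError(f"missing neighbour column {col!r} for offset {off}")
        g = sub[sub[col].isin(BASES)]
        e1 = g[g[label_col].astype(bool)]
        e0 = g[~g[label_col].astype(bool)]
        counts = np.array(
            [
                [int((e1[col] == b).sum()) for b in BASES],
                [int((e0[col] == b).sum()) for b in BASES],
            ],
            dtype=float,
        )
        row: dict = {"offset": off, "n_e1": len(e1), "n_e0": len(e0)}
        nonzero = counts.sum(axis=0) > 0  # drop absent nucleotides from the table
        eff = counts[:, nonzero]
        if len(e1) == 0 or len(e0) == 0 or nonzero.sum() < 2:
            row.update(chi2=np.nan, flag="degenerate")
        else:
            expected = np.outer(eff.sum(axis=1), eff.sum(axis=0)) / eff.sum()
            chi2 = float(((eff - expected) ** 2 / expected).sum())
            row.update(chi2=chi2, flag="low_expected" if (expected < 5).any() else "")
        for b in BASES:
            row[f"e1_{b}"] = (e1[col] == b).mean() if len(e1) else np.nan
            row[f"e0_{b}"] = (e0[col] == b).mean() if len(e0) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def neighbor_enrichment(
    sites: pd.DataFrame,
    offset: int,
    stratum: str | None = None,
    label_col: str = "is_edited",
) -> pd.DataFrame:
    """Enrichment factor per nucleotide at one neighbour offset.

    Baseline is the mean editing frequency over stratum sites whose
    neighbour at that offset is defined, so enrichments average to 1 with
    site-share weights.
    """
    col = f"up{-offset}" if offset < 0 else f"dn{offset}"
    sub = sites if stratum is None else sites[sites["kind"] == stratum]
    g = sub[sub[col].isin(BASES)]
    baseline = g[label_col].mean() if len(g) else np.nan
    rows = []
    for b in BASES:
        gb = g[g[col] == b]
        n = len(gb)
        k = int(gb[label_col].sum())
        rows.append(
            {
                "offset": offset,
                "stratum": stratum or "all",
                "nucleotide": b,
                "n_sites": n,
                "freq": k / n if n else np.nan,
                "enrichment": (k / n) / baseline if n and baseline > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided two-proportion z-test with pooled variance.

    Equivalent to the Pearson chi-square test (df = 1) on the 2x2 table,
    without continuity correction.  Returns the two-sided p-value.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0
    z = (p1 - p2) / se
    return float(2 * sps.norm.sf(abs(z)))


def bonferroni(p_values: Iterable[float], m: int | None = None) -> list[float]:
    """Bonferroni-adjusted p-values: min(1, p * m)."""
    p = list(p_values)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError(f"m={m} is smaller than the number of p-values ({len(p)})")
    return [min(1.0, v * m) for v in p]


def load_reference_joint_table() -> pd.DataFrame:
    """Packaged reference table of joint (up1, dn1, opNuc) editing contexts.

    Editing frequencies, enrichment factors and site counts per joint context
    among interior-loop sites, compiled from a large-scale survey of A-to-I
    editing in human Alu repeats.  Used to validate the shared-baseline
    definition of the enrichment factor: freq / enrichment must be the same
    for every row.
    """
    ref = importlib.resources.files("aluedit.data").joinpath("joint_context_reference.tsv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
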