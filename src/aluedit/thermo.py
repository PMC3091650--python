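"""Boltzmann-ensemble analysis of suboptimal RNA folds.

Given the discrete list of low free-energy structures predicted for a
neighborhood, each fold n receives the Boltzmann weight

    P_n = exp(-G_n / (R T)) / Z,      Z = sum_m exp(-G_m / (R T))

with G_n in kcal/mol, R the gas constant in kcal/(mol K) and T in Kelvin
(default 310.15 K, body temperature and the usual folding temperature).
The ensemble is exactly the supplied fold list; no re-enumeration or
partition-function calculation is performed.

For a site i, p_i^s is the total weight of folds under which position i is
classified into substructure kind s, and the structural entropy

    H_i = - sum_s p_i^s ln p_i^s        (nats)

measures how volatile the site's micro-structure is across the ensemble:
H = 0 when the site always occupies the same kind, up to ln 6 when it spends
equal weight in all six kinds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from aluedit.structure import KINDS, PairingTable, classify_substructures

#: gas constant, kcal mol^-1 K^-1
GAS_CONSTANT = 1.98717e-3

#: default folding temperature, Kelvin (37 degrees C)
BODY_TEMPERATURE = 310.15


def boltzmann_weights(energies, temperature: float = BODY_TEMPERATURE) -> np.ndarray:
    """Boltzmann probabilities for a list of free energies (kcal/mol).

    Computed with a max-shift so arbitrarily low energies stay finite; adding
    a constant to all energies leaves the weights unchanged.
    """
    g = np.asarray(list(energies), dtype=float)
    if g.size == 0:
        raise ValueError("at least one free energy is required")
    if not np.all(np.isfinite(g)):
        raise ValueError("free energies must be finite")
    x = -g / (GAS_CONSTANT * temperature)
    x -= x.max()
    w = np.exp(x)
    return w / w.sum()


@dataclass
class BoltzmannEnsemble:
    """A fold ensemble: structures with free energies at one temperature.

    All structures must be over the same sequence.  Classification of each
    fold is computed lazily and cached; ``kind_matrix`` row n gives the
    per-position substructure kind under fold n.
    """

    structures: list[PairingTable]
    temperature: float = BODY_TEMPERATURE
    _kind_matrix: list[list[str]] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.structures:
            raise ValueError("ensemble must contain at least one structure")
        seq0 = self.structures[0].sequence
        for pt in self.structures[1:]:
            if pt.sequence != seq0:
                raise ValueError(
                    "all structures in an ensemble must share one sequence "
                    f"(got lengths {len(seq0)} vs {len(pt.sequence)})"
                )
        if any(pt.free_energy is None for pt in self.structures):
            raise ValueError("every structure in an ensemble needs a free energy")

    def __len__(self) -> int:
        return len(self.structures)

    @property
    def energies(self) -> np.ndarray:
        return np.array([pt.free_energy for pt in self.structures], dtype=float)

    @property
    def weights(self) -> np.ndarray:
        return boltzmann_weights(self.energies, self.temperature)

    @property
    def ground_state_index(self) -> int:
        """Index of the minimum-free-energy fold (ties: first listed)."""
        return int(np.argmin(self.energies))

    @property
    def ground_state(self) -> PairingTable:
        return self.structures[self.ground_state_index]

    @property
    def kind_matrix(self) -> list[list[str]]:
        if self._kind_matrix is None:
            self._kind_matrix = [
                classify_substructures(pt).kind_of for pt in self.structures
            ]
        return self._kind_matrix


def substructure_probabilities(ensemble: BoltzmannEnsemble, site: int) -> dict[str, float]:
    """p^s vector for a 1-based position: Boltzmann-weighted kind indicator."""
    n = len(ensemble.structures[0])
    if not (1 <= site <= n):
        raise IndexError(f"site {site} out of range 1..{n}")
    w = ensemble.weights
    p = dict.fromkeys(KINDS, 0.0)
    for wn, kinds in zip(w, ensemble.kind_matrix):
        p[kinds[site]] += wn
    return p


def structural_entropy(p_vector) -> float:
    """Shannon entropy (nats) of a substructure probability vector.

    Accepts a mapping over kinds or any probability sequence; entries must be
    non-negative and sum to 1 within 1e-6.  0 * ln 0 is taken as 0.
    """
    if isinstance(p_vector, dict):
        p = np.array([p_vector.get(k, 0.0) for k in KINDS], dtype=float)
    else:
        p = np.asarray(list(p_vector), dtype=float)
    if np.any(p < -1e-12):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"probabilities must sum to 1 (got {p.sum():.8f})")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def ensemble_profiles(ensemble: BoltzmannEnsemble, sites) -> pd.DataFrame:
    """Per-site ensemble summary: p^s for each kind, H, ground-state kind.

    ``sites`` is an iterable of 1-based positions.  Vectorised over the whole
    ensemble: one classification per fold, then weighted indicator sums.
    """
    sites = list(sites)
    w = ensemble.weights
    kind_mat = ensemble.kind_matrix
    gs = kind_mat[ensemble.ground_state_index]
    kind_idx = {k: i for i, k in enumerate(KINDS)}
    p = np.zeros((len(sites), len(KINDS)))
    for wn, kinds in zip(w, kind_mat):
        for r, s in enumerate(sites):
            p[r, kind_idx[kinds[s]]] += wn
    nz = np.where(p > 0, p, 1.0)
    entropy = -(p * np.log(nz)).sum(axis=1)
    # kill float jitter so H = 0 sites are exactly 0 (they share quantile bins)
    entropy = np.round(np.maximum(entropy, 0.0), 9)
    out = pd.DataFrame(p, columns=[f"p_{k}" for k in KINDS])
    out.insert(0, "position", sites)
    out["entropy"] = entropy
    out["ground_state_kind"] = [gs[s] for s in sites]
    return out


def entropy_profile(
    sites: pd.DataFrame,
    n_bins: int = 10,
    strata: tuple[str, ...] = ("helix", "interior"),
    entropy_col: str = "entropy",
    label_col: str = "is_edited",
    stratum_col: str = "ground_state_kind",
) -> pd.DataFrame:
    """Editing frequency vs structural entropy, stratified by ground-state kind.

    Sites are binned into (up to) ``n_bins`` equal-count entropy bins per
    stratum.  Because many sites have exactly H = 0 (the same kind in every
    fold), a point mass at the minimum larger than one bin share becomes its
    own bin and the quantile bins cover the remaining sites.  Each row
    carries the bin's mean entropy, editing frequency and a Wilson 95% CI.
    A stratum that collapses to fewer than two bins is emitted unbinned with
    ``flag = "unbinned"``.
    """
    from aluedit.stats import wilson_interval

    rows = []
    for stratum in strata:
        sub = sites[sites[stratum_col] == stratum]
        if sub.empty:
            continue
        h = sub[entropy_col]
        bins: pd.Series | None
        try:
            if (h == h.min()).mean() > 1.0 / n_bins:
                bins = pd.Series("", index=sub.index, dtype=object)
                at_min = h == h.min()
                bins[at_min] = f"H={h.min():.3g}"
                if (~at_min).sum() >= max(n_bins - 1, 2):
                    bins[~at_min] = pd.qcut(
                        h[~at_min], q=n_bins - 1, duplicates="drop"
                    ).astype(str)
                else:
                    bins[~at_min] = "H>min"
            else:
                bins = pd.qcut(h, q=n_bins, duplicates="drop").astype(str)
        except (ValueError, IndexError):
            bins = None
        flag = ""
        if bins is None or bins.nunique() < 2:
            bins = pd.Series(["all"] * len(sub), index=sub.index)
            flag = "unbinned"
        stratum_rows = []
        for _, g in sub.groupby(bins, observed=True):
            n = len(g)
            k = int(g[label_col].sum())
            lo, hi = wilson_interval(k, n)
            stratum_rows.append(
                {
                    "stratum": stratum,
                    "entropy_mean": float(g[entropy_col].mean()),
                    "entropy_min": float(g[entropy_col].min()),
                    "entropy_max": float(g[entropy_col].max()),
                    "n_sites": n,
                    "n_edited": k,
                    "freq": k / n,
                    "ci_low": lo,
                    "ci_high": hi,
                    "flag": flag,
                }
            )
        stratum_rows.sort(key=lambda r: r["entropy_mean"])
        for bin_id, row in enumerate(stratum_rows):
            row["bin"] = bin_id
        rows.extend(stratum_rows)
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out[
            ["stratum", "bin", "entropy_mean", "entropy_min", "entropy_max",
             "n_sites", "n_edited", "freq", "ci_low", "ci_high", "flag"]
        ]
    return out
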