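"""Multinomial model of stochastic capsid assembly.

An AAV capsid is a T=1 icosahedral shell of 60 viral-protein (VP) subunits
drawn from up to three species (VP1, VP2, VP3) that share a common core
sequence but differ in their N-terminal extensions.  Under the stochastic
assembly model each capsid forms by 60 independent random draws from the
bulk pool of expressed VPs, so the probability of an integer stoichiometry
``(n1, n2, n3)`` with ``n1 + n2 + n3 = 60`` is multinomial::

    P(n1, n2, n3) = 60! / (n1! n2! n3!) * p1**n1 * p2**n2 * p3**n3

where ``(p1, p2, p3)`` are the bulk VP fractions.  For three species and 60
subunits there are C(62, 2) = 1,891 distinct stoichiometries, each with its
own capsid mass.  This module enumerates them, evaluates their
probabilities (in log space, via log-gamma), and derives the summary
quantities used downstream: marginal copy-number histograms, the modal
stoichiometry, the fraction of capsids lacking VP1 or VP2, and the exact
count of distinguishable subunit arrangements for a given stoichiometry.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binom

__all__ = [
    "VPRatio",
    "AssemblyModel",
    "CapsidEnsemble",
    "enumerate_compositions",
    "composition_probability",
    "build_ensemble",
    "marginal_count_distribution",
    "missing_species_fraction",
    "modal_composition",
    "configuration_count",
]

_NORM_TOL = 1e-9


class VPRatio:
    """Bulk VP fractions, i.e. the probabilities of drawing each species.

    Accepts any nonnegative weight triple (or pair/quadruple for the
    generalized model) and normalizes it, so percent triples (``6, 16, 78``),
    count ratios (``3, 10, 47``) and probability triples (``0.06, 0.16,
    0.78``) are all valid and equivalent up to scale.

    Parameters
    ----------
    *weights
        Nonnegative weights, one per VP species, either as separate
        arguments or as a single sequence.  Must not sum to zero.
    """

    __slots__ = ("probs",)

    def __init__(self, *weights: float):
        if len(weights) == 1 and isinstance(weights[0], (Sequence, np.ndarray)):
            weights = tuple(weights[0])
        w = np.asarray(weights, dtype=float)
        if w.ndim != 1 or w.size < 1 or w.size > 4:
            raise ValueError("expected between 1 and 4 VP weights")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError(f"VP weights must be finite and nonnegative, got {weights}")
        total = w.sum()
        if total <= 0:
            raise ValueError("VP weights must not all be zero")
        self.probs: tuple[float, ...] = tuple(w / total)

    @classmethod
    def parse(cls, text: str) -> "VPRatio":
        """Parse a ratio string such as ``"6:16:78"``, ``"6%:16%:78%"`` or
        ``"0.06,0.16,0.78"``."""
        parts = [p.strip().rstrip("%") for p in re.split(r"[:,;/\s]+", text.strip()) if p.strip()]
        try:
            weights = [float(p) for p in parts]
        except ValueError as exc:
            raise ValueError(
                f"cannot parse VP ratio {text!r}; expected e.g. '6:16:78' or '0.06,0.16,0.78'"
            ) from exc
        return cls(weights)

    @property
    def p_vp1(self) -> float:
        return self.probs[0]

    @property
    def p_vp2(self) -> float:
        return self.probs[1]

    @property
    def p_vp3(self) -> float:
        return self.probs[2]

    def __len__(self) -> int:
        return len(self.probs)

    def __iter__(self):
        return iter(self.probs)

    def __eq__(self, other) -> bool:
        return isinstance(other, VPRatio) and self.probs == other.probs

    def __hash__(self) -> int:
        return hash(self.probs)

    def __repr__(self) -> str:
        inner = ", ".join(f"{p:.6g}" for p in self.probs)
        return f"VPRatio({inner})"


@dataclass(frozen=True)
class AssemblyModel:
    """Geometry and masses of the assembling capsid.

    Parameters
    ----------
    vp_masses
        Monomer mass of each VP species in Da, VP1 first.  The number of
        species is taken from the length of this tuple (1-4 supported).
    n_subunits
        Total subunits per capsid (60 for the T=1 icosahedral AAV shell).
    adduct_mass
        Mass added once per assembled capsid, in Da, accounting for
        residual solvent adducts observed on intact particles (default
        2,800 Da).
    """

    vp_masses: tuple[float, ...]
    n_subunits: int = 60
    adduct_mass: float = 2800.0

    def __post_init__(self):
        object.__setattr__(self, "vp_masses", tuple(float(m) for m in self.vp_masses))
        if not 1 <= len(self.vp_masses) <= 4:
            raise ValueError("between 1 and 4 VP species are supported")
        if any(m <= 0 for m in self.vp_masses):
            raise ValueError("VP monomer masses must be strictly positive")
        if self.n_subunits < 1:
            raise ValueError("n_subunits must be >= 1")

    @property
    def n_species(self) -> int:
        return len(self.vp_masses)

    def capsid_mass(self, counts: Sequence[int]) -> float:
        """Mass (Da) of a capsid with the given per-species subunit counts."""
        return float(np.dot(counts, self.vp_masses)) + self.adduct_mass


@lru_cache(maxsize=32)
def _enumeration(n_subunits: int, n_species: int) -> tuple[np.ndarray, np.ndarray]:
    """Cached composition matrix and multinomial log-coefficients.

    Returns ``(counts, log_coeff)`` where ``counts`` has one row per
    composition in lexicographic order of the leading ``n_species - 1``
    counts and ``log_coeff[i] = log( n! / prod_j counts[i, j]! )``.
    """
    rows: list[tuple[int, ...]] = []

    def rec(prefix: tuple[int, ...], remaining: int, depth: int):
        if depth == n_species - 1:
            rows.append(prefix + (remaining,))
            return
        for c in range(remaining + 1):
            rec(prefix + (c,), remaining - c, depth + 1)

    rec((), n_subunits, 0)
    counts = np.array(rows, dtype=np.int64)
    log_coeff = gammaln(n_subunits + 1) - gammaln(counts + 1).sum(axis=1)
    return counts, log_coeff


def enumerate_compositions(model: AssemblyModel) -> list[tuple[int, ...]]:
    """All distinct stoichiometries of the model, as count tuples.

    The order is deterministic: lexicographic in the leading counts, so for
    three species it sorts by ``(n_vp1, n_vp2)`` with ``n_vp3`` implied.
    For 3 species x 60 subunits this yields the 1,891 co-occurring capsid
    stoichiometries of the stochastic assembly model.
    """
    counts, _ = _enumeration(model.n_subunits, model.n_species)
    return [tuple(int(c) for c in row) for row in counts]


def _log_probabilities(counts: np.ndarray, log_coeff: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Vectorized multinomial log-pmf; zero-probability species handled exactly."""
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    safe = np.where(np.isfinite(logp), logp, 0.0)
    out = log_coeff + counts @ safe
    impossible = ((counts > 0) & (probs == 0.0)[None, :]).any(axis=1)
    out[impossible] = -np.inf
    return out


def composition_probability(
    comp: Sequence[int], ratio: VPRatio, model: AssemblyModel
) -> float:
    """Multinomial probability of one capsid stoichiometry.

    Evaluated in log space via log-gamma (60! overflows naive arithmetic)
    and exponentiated at the end.  A composition requiring a species with
    zero bulk probability has probability exactly 0.
    """
    comp = tuple(int(c) for c in comp)
    if len(comp) != model.n_species:
        raise ValueError(f"composition {comp} has {len(comp)} species, model has {model.n_species}")
    if any(c < 0 for c in comp) or sum(comp) != model.n_subunits:
        raise ValueError(f"composition {comp} must be nonnegative and sum to {model.n_subunits}")
    if len(ratio) != model.n_species:
        raise ValueError("ratio and model disagree on the number of species")
    probs = np.asarray(ratio.probs)
    counts = np.asarray(comp, dtype=np.int64)[None, :]
    log_coeff = gammaln(model.n_subunits + 1) - gammaln(counts + 1).sum(axis=1)
    return float(np.exp(_log_probabilities(counts, log_coeff, probs))[0])


@dataclass
class CapsidEnsemble:
    """Every stoichiometry of a model with its capsid mass and probability.

    ``counts`` has one row per stoichiometry (enumeration order), ``masses``
    are in Da and include the per-capsid adduct mass, and ``probabilities``
    are the multinomial weights (summing to 1 over the full enumeration).
    """

    counts: np.ndarray
    masses: np.ndarray
    probabilities: np.ndarray
    model: AssemblyModel
    ratio: VPRatio

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def mean_mass(self) -> float:
        """Probability-weighted average capsid mass in Da."""
        return float(np.dot(self.probabilities, self.masses) / self.probabilities.sum())

    def truncate(self, min_rel_probability: float) -> "CapsidEnsemble":
        """Drop entries below ``min_rel_probability`` x the modal probability.

        Probabilities are not renormalized; the retained entries keep their
        multinomial weights, so a sufficiently small threshold leaves the
        simulated spectrum unchanged to within numerical noise.
        """
        keep = self.probabilities >= min_rel_probability * self.probabilities.max()
        return CapsidEnsemble(
            self.counts[keep], self.masses[keep], self.probabilities[keep], self.model, self.ratio
        )

    def as_dataframe(self) -> pd.DataFrame:
        cols = {f"n_vp{i + 1}": self.counts[:, i] for i in range(self.counts.shape[1])}
        cols["mass_da"] = self.masses
        cols["probability"] = self.probabilities
        return pd.DataFrame(cols)

    def to_tsv(self, path) -> None:
        self.as_dataframe().to_csv(path, sep="\t", index=False)

    def heatmap_matrix(self) -> pd.DataFrame:
        """Probability matrix indexed by n_vp1 (rows) and n_vp2 (columns).

        Only defined for the three-species model; infeasible cells
        (n_vp1 + n_vp2 > n_subunits) are NaN.
        """
        if self.model.n_species != 3:
            raise ValueError("heat-map export requires the 3-species model")
        n = self.model.n_subunits
        mat = np.full((n + 1, n + 1), np.nan)
        mat[self.counts[:, 0], self.counts[:, 1]] = self.probabilities
        return pd.DataFrame(mat, index=pd.RangeIndex(n + 1, name="n_vp1"),
                            columns=pd.RangeIndex(n + 1, name="n_vp2"))


def build_ensemble(ratio: VPRatio, model: AssemblyModel) -> CapsidEnsemble:
    """Enumerate all stoichiometries with their masses and probabilities."""
    if len(ratio) != model.n_species:
        raise ValueError("ratio and model disagree on the number of species")
    counts, log_coeff = _enumeration(model.n_subunits, model.n_species)
    probs = np.exp(_log_probabilities(counts, log_coeff, np.asarray(ratio.probs)))
    masses = counts @ np.asarray(model.vp_masses) + model.adduct_mass
    return CapsidEnsemble(counts, masses, probs, model, ratio)


def marginal_count_distribution(
    ratio: VPRatio, model: AssemblyModel, species: int
) -> np.ndarray:
    """Probability of a capsid carrying 0..n_subunits copies of one species.

    The marginal of a multinomial is binomial, so this equals
    ``Binom(n_subunits, p_species)`` evaluated on 0..n_subunits.
    """
    if not 0 <= species < model.n_species:
        raise ValueError(f"species index {species} out of range for {model.n_species} species")
    k = np.arange(model.n_subunits + 1)
    return binom.pmf(k, model.n_subunits, ratio.probs[species])


def missing_species_fraction(ratio: VPRatio, model: AssemblyModel) -> float:
    """Fraction of capsids that lack VP1 entirely or lack VP2 entirely.

    By inclusion-exclusion over the multinomial,
    ``P(n1=0 or n2=0) = (1-p1)^n + (1-p2)^n - (1-p1-p2)^n``.
    """
    if model.n_species != 3 or len(ratio) != 3:
        raise ValueError("missing-species fraction is defined for the 3-species model")
    p1, p2, _ = ratio.probs
    n = model.n_subunits
    return (1.0 - p1) ** n + (1.0 - p2) ** n - (1.0 - p1 - p2) ** n


def modal_composition(ratio: VPRatio, model: AssemblyModel) -> tuple[tuple[int, ...], float]:
    """Most probable stoichiometry and its probability.

    Ties are broken by the deterministic enumeration order (first wins).
    """
    ens = build_ensemble(ratio, model)
    i = int(np.argmax(ens.probabilities))
    return tuple(int(c) for c in ens.counts[i]), float(ens.probabilities[i])


def configuration_count(comp: Sequence[int]) -> int:
    """Exact number of distinguishable subunit arrangements of a stoichiometry.

    This is the multinomial coefficient ``n! / prod_i n_i!`` computed in
    arbitrary-precision integer arithmetic, counting position-labelled
    placements of the subunits on the 60 sites (icosahedral symmetry can
    reduce the number of truly distinct configurations by at most 60-fold).
    """
    comp = [int(c) for c in comp]
    if any(c < 0 for c in comp):
        raise ValueError("counts must be nonnegative")
    total = sum(comp)
    out = math.factorial(total)
    for c in comp:
        out //= math.factorial(c)
    return out
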