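"""Population-genetic and diversity statistics on windowed sub-alignments.

All statistics live on the *per-alignment* (total) scale that Tajima's D
requires: π is the mean number of differences per sequence pair over the
whole sub-alignment, and Watterson's θ_w = S/a₁ is on the same scale.
Per-site variants are obtained by dividing by the column count.

Tajima's D compares π with θ_w, normalised by the variance expected under
neutrality for a sample of n sequences:

    a₁ = Σ_{i<n} 1/i            a₂ = Σ_{i<n} 1/i²
    b₁ = (n+1)/(3(n−1))         b₂ = 2(n²+n+3)/(9n(n−1))
    c₁ = b₁ − 1/a₁              c₂ = b₂ − (n+2)/(a₁n) + a₂/a₁²
    e₁ = c₁/a₁                  e₂ = c₂/(a₁² + a₂)
    D  = (π − S/a₁) / √(e₁S + e₂S(S−1))

D is *null* (None, not 0) when S = 0, when n < 3, or when the variance
estimate e₁S + e₂S(S−1) is not positive: with no segregating sites the
denominator vanishes, and for n ∈ {2, 3} the coefficients c₁ and c₂ are
identically zero. Positive D indicates an excess of intermediate-frequency
variants (balancing selection); negative D an excess of rare variants.

The core statistics demand clean alignments — the window's gap policy must
already have been applied — and raise on residual gap or ambiguity
characters. :func:`diversity_summary` additionally offers pairwise deletion
for alignments that intentionally retain gaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import ContractViolationError, InsufficientDataError
from .seqalign import AlignmentData

_INVALID = {"dna": {"-", "N"}, "protein": {"-", "X"}}


def _check_clean(aln: AlignmentData) -> None:
    bad = set("".join(aln.rows)) & _INVALID[aln.alphabet]
    if bad:
        raise ContractViolationError(
            f"alignment still contains gap/ambiguity characters {sorted(bad)}; "
            "apply the gap policy first"
        )


def _require_rows(aln: AlignmentData, k: int) -> None:
    if aln.n < k:
        raise InsufficientDataError(f"need at least {k} sequences, got {aln.n}")


def harmonic(n: int, power: int = 1) -> float:
    """Σ_{i=1}^{n-1} 1/i^power (a₁ for power=1, a₂ for power=2)."""
    return sum(1.0 / i**power for i in range(1, n))


def segregating_sites(aln: AlignmentData) -> int:
    """Number of columns with more than one observed state."""
    _require_rows(aln, 2)
    _check_clean(aln)
    return sum(
        1 for c in range(1, aln.length + 1) if len(set(aln.column(c))) > 1
    )


def nucleotide_diversity(aln: AlignmentData) -> float:
    """Mean pairwise difference count π (per alignment, not per site)."""
    _require_rows(aln, 2)
    _check_clean(aln)
    if aln.length == 0:
        return 0.0
    mat = np.array([list(r.encode()) for r in aln.rows], dtype=np.uint8)
    total = 0
    n_pairs = 0
    for i, j in combinations(range(aln.n), 2):
        total += int((mat[i] != mat[j]).sum())
        n_pairs += 1
    return total / n_pairs


def nucleotide_diversity_per_site(aln: AlignmentData) -> float:
    if aln.length == 0:
        raise InsufficientDataError("zero-column alignment has no per-site diversity")
    return nucleotide_diversity(aln) / aln.length


def wattersons_theta(aln: AlignmentData) -> float:
    """Watterson's estimator S/a₁ on the per-alignment scale."""
    _require_rows(aln, 2)
    return segregating_sites(aln) / harmonic(aln.n)


def tajimas_d(aln: AlignmentData) -> float | None:
    """Tajima's D, or None when S = 0, n < 3, or the variance is degenerate."""
    _require_rows(aln, 2)
    S = segregating_sites(aln)
    if S == 0 or aln.n < 3:
        return None
    pi = nucleotide_diversity(aln)
    return _tajimas_d_from_summary(pi, S, aln.n)


def _tajimas_d_from_summary(pi: float, S: int, n: int) -> float | None:
    if S == 0 or n < 3:
        return None
    a1 = harmonic(n)
    a2 = harmonic(n, power=2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    variance = e1 * S + e2 * S * (S - 1)
    if variance <= 0:
        # c1 and c2 vanish identically at n = 3, so the variance estimate is
        # zero there for any S and D is undefined
        return None
    return (pi - S / a1) / math.sqrt(variance)


def shannon_entropy_profile(aln: AlignmentData) -> np.ndarray:
    """Per-column Shannon entropy in bits over observed states."""
    _require_rows(aln, 1)
    _check_clean(aln)
    out = np.empty(aln.length)
    for c in range(1, aln.length + 1):
        col = aln.column(c)
        counts = np.array([col.count(s) for s in set(col)], dtype=float)
        p = counts / counts.sum()
        out[c - 1] = float(-(p * np.log2(p)).sum())
    return out


def shannon_entropy(aln: AlignmentData) -> float | None:
    """Mean per-column entropy over the window; None for zero columns."""
    if aln.length == 0:
        return None
    return float(shannon_entropy_profile(aln).mean())


@dataclass
class DiversitySummary:
    n: int
    L: int
    S: int
    pi_total: float
    theta_w: float
    tajimas_d: float | None


def diversity_summary(aln: AlignmentData) -> DiversitySummary:
    """n, L, S, π, θ_w and D in one pass.

    Clean alignments use the strict statistics above. If gap/ambiguity
    characters remain (the ``pairwise`` gap policy), pairwise deletion is
    used instead: S counts columns with ≥2 distinct valid states, and each
    sequence pair is compared over the columns where both carry valid
    states.
    """
    _require_rows(aln, 2)
    invalid = _INVALID[aln.alphabet]
    if not set("".join(aln.rows)) & invalid:
        S = segregating_sites(aln)
        pi = nucleotide_diversity(aln)
    else:
        S = 0
        for c in range(1, aln.length + 1):
            states = set(aln.column(c)) - invalid
            if len(states) > 1:
                S += 1
        mat = np.array([list(r) for r in aln.rows])
        valid = ~np.isin(mat, sorted(invalid))
        total = 0.0
        n_pairs = 0
        for i, j in combinations(range(aln.n), 2):
            both = valid[i] & valid[j]
            total += int(((mat[i] != mat[j]) & both).sum())
            n_pairs += 1
        pi = total / n_pairs
    return DiversitySummary(
        n=aln.n,
        L=aln.length,
        S=S,
        pi_total=pi,
        theta_w=S / harmonic(aln.n),
        tajimas_d=_tajimas_d_from_summary(pi, S, aln.n),
    )
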