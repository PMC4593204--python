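"""Independent reference implementations used only to check the package.

Each oracle takes a deliberately different computational route from the
implementation it validates: exact rational arithmetic instead of
log-gamma sums, regex matching instead of set-intersection scanning, and
dense grid search instead of EM.
"""

from __future__ import annotations

import itertools
import re
from fractions import Fraction
from math import comb
from typing import Dict, List, Sequence, Tuple

import numpy as np

IUPAC_REGEX = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]", "K": "[GT]", "M": "[AC]",
    "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}
IUPAC_BASES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {
    "A": "T", "T": "A", "C": "G", "G": "C", "R": "Y", "Y": "R", "S": "S",
    "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def fisher_oracle(table: Sequence[Sequence[int]], tie_rtol: float = 1e-7) -> float:
    """Two-sided point-probability Fisher p by exact rational enumeration."""
    t = [list(map(int, row)) for row in table]
    cols = [sum(col) for col in zip(*t)]
    r0 = sum(t[0])
    n = sum(map(sum, t))
    if r0 == 0 or r0 == n or 0 in cols:
        return 1.0
    denom = comb(n, r0)

    def prob(first_row: Sequence[int]) -> Fraction:
        num = 1
        for c, x in zip(cols, first_row):
            num *= comb(c, x)
        return Fraction(num, denom)

    p_obs = prob(t[0])
    cutoff = p_obs * (Fraction(1) + Fraction(tie_rtol).limit_denominator(10**12))
    total = Fraction(0)
    for combo in itertools.product(*[range(c + 1) for c in cols[:-1]]):
        last = r0 - sum(combo)
        if 0 <= last <= cols[-1]:
            p = prob(list(combo) + [last])
            if p <= cutoff:
                total += p
    return float(total)


def fisher_2x2_oracle_fast(a: int, b: int, c: int, d: int, tie_ppm: int = 10**7) -> float:
    """Exact 2x2 point-probability p using integer hypergeometric numerators.

    All tables sharing the margins share the denominator C(n, r0), so point
    probabilities compare as integer numerators; the tie tolerance is
    applied as an exact rational inequality.
    """
    r0, c0, c1 = a + b, a + c, b + d
    n = r0 + c + d
    if r0 == 0 or r0 == n or c0 == 0 or c1 == 0:
        return 1.0
    num_obs = comb(c0, a) * comb(c1, b)
    total = 0
    for x in range(max(0, r0 - c1), min(r0, c0) + 1):
        num = comb(c0, x) * comb(c1, r0 - x)
        if num * tie_ppm <= num_obs * (tie_ppm + 1):
            total += num
    return total / comb(n, r0)


def hwe_oracle(n_11: int, n_12: int, n_22: int, tie_rtol: float = 1e-7) -> float:
    """Exact conditional Hardy-Weinberg p by rational enumeration.

    P(n12 | n, allele counts) = n! / (n11! n12! n22!) * 2**n12 * na! * nb! / (2n)!
    """
    from math import factorial

    n = n_11 + n_12 + n_22
    na = 2 * n_11 + n_12
    nb = 2 * n_22 + n_12
    rare = min(na, nb)
    if rare == 0:
        return 1.0

    def prob(het: int) -> Fraction:
        rare_hom = (rare - het) // 2
        common_hom = n - het - rare_hom
        return Fraction(
            factorial(n) * 2**het * factorial(na) * factorial(nb),
            factorial(het) * factorial(rare_hom) * factorial(common_hom) * factorial(2 * n),
        )

    p_obs = prob(n_12)
    cutoff = p_obs * (Fraction(1) + Fraction(tie_rtol).limit_denominator(10**12))
    return float(sum(prob(h) for h in range(rare % 2, rare + 1, 2) if prob(h) <= cutoff))


def iupac_match_oracle(sequence: str, pattern: str) -> List[Tuple[int, str]]:
    """Plus-strand window matches via regex with explicit base-set semantics.

    Subject ambiguity codes are expanded: a window matches if some
    concretisation of every subject base satisfies the pattern class.
    Returns (start, site) pairs.
    """
    out = []
    L = len(pattern)
    for i in range(len(sequence) - L + 1):
        window = sequence[i : i + L]
        ok = True
        for sb, pb in zip(window, pattern):
            if not any(
                re.fullmatch(IUPAC_REGEX[pb], concrete)
                for concrete in IUPAC_BASES[sb]
            ):
                ok = False
                break
        if ok:
            out.append((i, window))
    return out


def iupac_scan_oracle(sequence: str, pattern: str) -> List[Tuple[int, str, str]]:
    """Both-strand hits as (plus_start, strand, site-on-motif-strand)."""
    L = len(pattern)
    n = len(sequence)
    hits = [(start, "+", site) for start, site in iupac_match_oracle(sequence, pattern)]
    for start_rc, site in iupac_match_oracle(revcomp(sequence), pattern):
        hits.append((n - start_rc - L, "-", site))
    return sorted(hits)


def em_grid_oracle(
    joint_counts: Sequence[Sequence[int]],
    coarse: float = 0.005,
    fine: float = 0.0005,
) -> np.ndarray:
    """Maximum-likelihood haplotype frequencies by dense grid search.

    Coarse sweep of the 3-simplex followed by a fine local sweep around the
    coarse optimum; resolution of the result is ``fine``.
    Returns (f11, f12, f21, f22).
    """
    j = np.asarray(joint_counts, dtype=float)

    def loglik(f11, f12, f21, f22):
        probs = np.stack(
            [
                f11**2, 2 * f11 * f12, f12**2,
                2 * f11 * f21, 2 * (f11 * f22 + f12 * f21), 2 * f12 * f22,
                f21**2, 2 * f21 * f22, f22**2,
            ],
            axis=-1,
        )
        w = j.reshape(-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = np.log(probs)
        lp = np.where(w > 0, lp, 0.0)
        lp = np.where(np.isfinite(lp), lp, -np.inf)
        return (w * lp).sum(axis=-1)

    def sweep(grid11, grid12, grid21):
        best, arg = -np.inf, None
        for f11_value in grid11:
            g12, g21 = np.meshgrid(grid12, grid21, indexing="ij")
            f11 = np.full_like(g12, f11_value)
            f22 = 1.0 - f11 - g12 - g21
            valid = f22 >= -1e-12
            ll = loglik(f11, g12, g21, np.clip(f22, 0.0, None))
            ll = np.where(valid, ll, -np.inf)
            k = np.argmax(ll)
            if ll.flat[k] > best:
                best = ll.flat[k]
                arg = (f11_value, g12.flat[k], g21.flat[k], max(f22.flat[k], 0.0))
        return best, arg

    axis = np.arange(0.0, 1.0 + coarse / 2, coarse)
    _, (f11, f12, f21, f22) = sweep(axis, axis, axis)

    def local(center):
        lo = max(0.0, center - 2 * coarse)
        return np.arange(lo, min(1.0, center + 2 * coarse) + fine / 2, fine)

    _, arg = sweep(local(f11), local(f12), local(f21))
    return np.array([arg[0], arg[1], arg[2], arg[3]])


def pwm_matrix_oracle(sites: Sequence[str], pseudocount: float = 0.5) -> Dict[str, list]:
    """Column probabilities recomputed with plain Python dicts."""
    L = len(sites[0])
    cols = []
    for j in range(L):
        counts = {b: pseudocount for b in "ACGT"}
        for s in sites:
            counts[s[j]] += 1
        total = sum(counts.values())
        cols.append({b: counts[b] / total for b in "ACGT"})
    return {b: [col[b] for col in cols] for b in "ACGT"}


def pwm_best_score_oracle(
    sequence: str, sites: Sequence[str], pseudocount: float = 0.5
) -> float:
    """Best both-strand log2-odds window score against a uniform background."""
    import math

    probs = pwm_matrix_oracle(sites, pseudocount)
    L = len(sites[0])
    best = -math.inf
    for subject in (sequence, revcomp(sequence)):
        for i in range(len(subject) - L + 1):
            score = sum(
                math.log2(probs[subject[i + j]][j] / 0.25) for j in range(L)
            )
            best = max(best, score)
    return best
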