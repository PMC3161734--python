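"""Brute-force reference enumeration of elementary flux modes.

Independent of the double description engine: for every subset ``T`` of the
split (all-irreversible) reaction columns, a flux vector with support
exactly ``T`` is elementary iff the submatrix ``S[:, T]`` has nullity one
and its kernel vector is strictly nonzero on all of ``T`` with a consistent
sign.  This is exponential in the reaction count and is intended for small
test networks only (the practical limit is ~16 split columns).

Kernel computation uses exact Gauss-Jordan elimination over rationals.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Sequence

from .efm import EfmSet, _unsplit_and_canonicalise, split_internal_matrix
from .network import MetabolicNetwork

__all__ = ["bruteforce_efms", "rational_kernel"]


def rational_kernel(rows: Sequence[Sequence[Fraction]], n_cols: int) -> list[list[Fraction]]:
    """Basis of the right kernel of a rational matrix (list of rows)."""
    # reduced row echelon form
    M = [list(map(Fraction, r)) for r in rows]
    pivots: list[int] = []
    r = 0
    for c in range(n_cols):
        pr = next((i for i in range(r, len(M)) if M[i][c] != 0), None)
        if pr is None:
            continue
        M[r], M[pr] = M[pr], M[r]
        pv = M[r][c]
        M[r] = [x / pv for x in M[r]]
        for i in range(len(M)):
            if i != r and M[i][c] != 0:
                f = M[i][c]
                M[i] = [a - f * b for a, b in zip(M[i], M[r])]
        pivots.append(c)
        r += 1
        if r == len(M):
            break
    free = [c for c in range(n_cols) if c not in pivots]
    basis = []
    for fc in free:
        v = [Fraction(0)] * n_cols
        v[fc] = Fraction(1)
        for pr, pc in enumerate(pivots):
            v[pc] = -M[pr][fc]
        basis.append(v)
    return basis


def bruteforce_efms(net: MetabolicNetwork, max_columns: int = 18) -> EfmSet:
    """Enumerate EFMs by exhaustive support-subset checking.

    Produces the same canonical integer vectors, in the same deterministic
    order, as :func:`chlamyflux.efm.enumerate_efms`.
    """
    rows, columns = split_internal_matrix(net)
    n = len(columns)
    if n > max_columns:
        raise ValueError(
            f"{n} split columns exceed the brute-force limit of {max_columns}"
        )
    frac_rows = [[Fraction(x) for x in row] for row in rows]
    row_masks = [sum(1 << k for k in range(n) if row[k]) for row in rows]
    # masks of forward/backward split pairs: any strict superset of a pair
    # contains the two-cycle in its kernel and cannot be elementary
    rev_idx = {}
    for k, (j, sgn) in enumerate(columns):
        rev_idx.setdefault(j, {})[sgn] = k
    pair_masks = [
        (1 << d[+1]) | (1 << d[-1]) for d in rev_idx.values() if len(d) == 2
    ]
    found_masks: list[int] = []
    rays: list[list[int]] = []
    for mask in range(1, 1 << n):
        # a metabolite touched by exactly one active reaction cannot balance
        if any((rm & mask).bit_count() == 1 for rm in row_masks):
            continue
        if any(pm & mask == pm and pm != mask for pm in pair_masks):
            continue
        # support-minimality: strict supersets of found supports are never
        # elementary (ascending mask order visits subsets first)
        if any(fm & mask == fm and fm != mask for fm in found_masks):
            continue
        cols = [k for k in range(n) if mask >> k & 1]
        sub = [[fr[k] for k in cols] for fr in frac_rows]
        kernel = rational_kernel(sub, len(cols))
        if len(kernel) != 1:
            continue
        w = kernel[0]
        if any(x == 0 for x in w):
            continue  # support would be a proper subset of T
        if all(x > 0 for x in w):
            pass
        elif all(x < 0 for x in w):
            w = [-x for x in w]
        else:
            continue  # not sign-feasible in the non-negative split cone
        scale = math.lcm(*(x.denominator for x in w))
        ints = [int(x * scale) for x in w]
        g = math.gcd(*ints)
        ray = [0] * n
        for k, val in zip(cols, ints):
            ray[k] = val // g
        rays.append(ray)
        found_masks.append(mask)
    reversible_flags = [r.reversible for r in net.reactions]
    vectors = _unsplit_and_canonicalise(rays, columns, len(net.reactions), reversible_flags)
    return EfmSet(net, tuple(net.reaction_ids), vectors, stats={"algorithm": "bruteforce"})
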