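"""Low-level permutation and triangular bit-code machinery.

A graphlet on vertices 0..n-1 is encoded as an integer *code*: the strict
lower triangle of its adjacency matrix read row-major (rows 1..n-1, columns
0..r-1), with the first triangle position as the most significant bit.  With
this layout, lexicographic comparison of the bit strings coincides with
integer comparison of the codes, so the canonical form of a graphlet is
simply the minimum code over all vertex permutations.

Everything here is exhaustive over permutations (n! in general, (n-1)! when
vertex 0 is pinned).  That is the intended mechanism for this tool's working
range (n <= 7); no refinement-based isomorphism shortcuts are used.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations


@lru_cache(maxsize=None)
def pair_positions(n: int) -> tuple[tuple[int, int], ...]:
    """Triangle positions (r, c) with r > c, in row-major reading order."""
    return tuple((r, c) for r in range(1, n) for c in range(r))


@lru_cache(maxsize=None)
def pair_index(n: int) -> dict[tuple[int, int], int]:
    return {p: i for i, p in enumerate(pair_positions(n))}


def code_length(n: int) -> int:
    return n * (n - 1) // 2


@lru_cache(maxsize=None)
def all_perms(n: int) -> tuple[tuple[int, ...], ...]:
    return tuple(permutations(range(n)))


@lru_cache(maxsize=None)
def perms_fixing_zero(n: int) -> tuple[tuple[int, ...], ...]:
    if n == 1:
        return ((0,),)
    return tuple((0,) + p for p in permutations(range(1, n)))


@lru_cache(maxsize=None)
def position_maps(n: int, fix_zero: bool = False) -> tuple[tuple[int, ...], ...]:
    """For each permutation, the source bit position feeding each target position.

    Permutations map old labels to new labels; the bit at target position
    (r, c) of the permuted code is the bit at position {perm^-1(r), perm^-1(c)}
    of the original code.
    """
    perms = perms_fixing_zero(n) if fix_zero else all_perms(n)
    pairs = pair_positions(n)
    idx = pair_index(n)
    maps = []
    for perm in perms:
        inv = [0] * n
        for old, new in enumerate(perm):
            inv[new] = old
        maps.append(
            tuple(
                idx[(max(inv[r], inv[c]), min(inv[r], inv[c]))] for (r, c) in pairs
            )
        )
    return tuple(maps)


def code_from_edges(n: int, edges) -> int:
    length = code_length(n)
    idx = pair_index(n)
    code = 0
    for u, v in edges:
        j = idx[(max(u, v), min(u, v))]
        code |= 1 << (length - 1 - j)
    return code


def edges_from_code(n: int, code: int) -> frozenset[tuple[int, int]]:
    length = code_length(n)
    pairs = pair_positions(n)
    return frozenset(
        (c, r) for j, (r, c) in enumerate(pairs) if code >> (length - 1 - j) & 1
    )


def permute_code(code: int, posmap: tuple[int, ...], length: int) -> int:
    out = 0
    for j, src in enumerate(posmap):
        if code >> (length - 1 - src) & 1:
            out |= 1 << (length - 1 - j)
    return out


@lru_cache(maxsize=262144)
def canonical_code(n: int, code: int, fix_zero: bool = False) -> int:
    length = code_length(n)
    best = code
    for pm in position_maps(n, fix_zero):
        v = permute_code(code, pm, length)
        if v < best:
            best = v
    return best


def canonical_code_perm(
    n: int, code: int, fix_zero: bool = False
) -> tuple[int, tuple[int, ...]]:
    """Canonical code plus the first permutation (in itertools order) achieving it."""
    length = code_length(n)
    perms = perms_fixing_zero(n) if fix_zero else all_perms(n)
    maps = position_maps(n, fix_zero)
    best = None
    best_perm = None
    for perm, pm in zip(perms, maps):
        v = permute_code(code, pm, length)
        if best is None or v < best:
            best, best_perm = v, perm
    return best, best_perm


def automorphism_perms(
    n: int, code: int, fix_zero: bool = False
) -> tuple[tuple[int, ...], ...]:
    """All permutations (optionally pinning vertex 0) preserving the edge set."""
    length = code_length(n)
    perms = perms_fixing_zero(n) if fix_zero else all_perms(n)
    maps = position_maps(n, fix_zero)
    return tuple(
        perm for perm, pm in zip(perms, maps) if permute_code(code, pm, length) == code
    )


def connected_code(n: int, code: int) -> bool:
    """Connectivity check directly on a triangle code."""
    if n == 1:
        return True
    length = code_length(n)
    nbr = [0] * n
    for j, (r, c) in enumerate(pair_positions(n)):
        if code >> (length - 1 - j) & 1:
            nbr[r] |= 1 << c
            nbr[c] |= 1 << r
    seen = 1
    frontier = 1
    while frontier:
        v = frontier.bit_length() - 1
        frontier &= ~(1 << v)
        new = nbr[v] & ~seen
        seen |= new
        frontier |= new
    return seen == (1 << n) - 1
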