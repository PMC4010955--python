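"""Permutations and sign flips under exchangeability-block structure.

Two error assumptions drive the construction: *exchangeable errors* (EE)
permit row permutations, *independent and symmetric errors* (ISE) permit
sign flips; when both hold the two are combined.  Exchangeability blocks
restrict the set: ``within`` blocks shuffle rows inside each block only
(sign flips remain unrestricted), ``whole`` blocks move equally-sized blocks
as intact units (sign flips act per block).

A shuffling is stored as an index permutation plus a +/-1 sign vector; signs
are applied before the permutation.  The set of shufflings always contains
the identity first, so the observed statistic is part of its own reference
distribution and the smallest attainable p-value is 1/J.

When the full set is small enough it is enumerated exhaustively and
without duplicates: permutations that merely swap identical design rows are
synonymous and generated once (multiset enumeration), sign-flip patterns are
indexed by radix-2 integers.  Otherwise random shufflings are drawn by
conditional Monte Carlo (CMC); duplicates are permitted by default.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from sympy.utilities.iterables import multiset_permutations

__all__ = [
    "ExchangeabilityBlocks",
    "Shuffling",
    "ShufflingSet",
    "count_max_shufflings",
    "enumerate_shufflings",
    "apply_shuffling",
]


@dataclass(frozen=True)
class ExchangeabilityBlocks:
    """Block labels plus the shuffling mode they imply."""

    labels: np.ndarray
    mode: str = "within"  # {"unrestricted", "within", "whole"}

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 1 or lab.size == 0:
            raise ValueError("block labels must be a nonempty 1-D vector")
        if self.mode not in ("unrestricted", "within", "whole"):
            raise ValueError(f"unknown block mode {self.mode!r}")
        object.__setattr__(self, "labels", lab)
        if self.mode == "whole":
            sizes = self.sizes
            if len(set(sizes)) > 1:
                raise ValueError(
                    "whole-block shuffling requires equally sized blocks, "
                    f"got sizes {sorted(set(sizes))}"
                )

    @classmethod
    def unrestricted(cls, N: int) -> "ExchangeabilityBlocks":
        return cls(np.zeros(N, dtype=int), mode="unrestricted")

    @property
    def N(self) -> int:
        return self.labels.size

    @property
    def block_indices(self) -> list[np.ndarray]:
        if self.mode == "unrestricted":
            return [np.arange(self.N)]
        blocks = np.unique(self.labels)
        return [np.where(self.labels == b)[0] for b in blocks]

    @property
    def n_blocks(self) -> int:
        return len(self.block_indices)

    @property
    def sizes(self) -> list[int]:
        return [len(ix) for ix in self.block_indices]


@dataclass(frozen=True)
class Shuffling:
    """Sign flips followed by a row permutation: row i of the output is
    ``signs[perm[i]] * row perm[i]`` of the input."""

    perm: np.ndarray
    signs: np.ndarray

    def __post_init__(self):
        perm = np.asarray(self.perm, dtype=np.intp)
        signs = np.asarray(self.signs, dtype=np.int8)
        if perm.shape != signs.shape or perm.ndim != 1:
            raise ValueError("perm and signs must be 1-D vectors of equal length")
        if not np.array_equal(np.sort(perm), np.arange(perm.size)):
            raise ValueError("perm is not a permutation of 0..N-1")
        if not np.all(np.abs(signs) == 1):
            raise ValueError("signs must be +/-1")
        object.__setattr__(self, "perm", perm)
        object.__setattr__(self, "signs", signs)

    @property
    def N(self) -> int:
        return self.perm.size

    @property
    def is_identity(self) -> bool:
        return bool(
            np.array_equal(self.perm, np.arange(self.N)) and np.all(self.signs == 1)
        )

    def inverse(self) -> "Shuffling":
        inv = np.empty_like(self.perm)
        inv[self.perm] = np.arange(self.N)
        return Shuffling(perm=inv, signs=self.signs[self.perm])

    @classmethod
    def identity(cls, N: int) -> "Shuffling":
        return cls(perm=np.arange(N), signs=np.ones(N, dtype=np.int8))

    def key(self) -> bytes:
        return self.perm.tobytes() + self.signs.tobytes()


@dataclass(frozen=True)
class ShufflingSet:
    shufflings: tuple
    regime: str  # {"ee", "ise", "both"}
    method_of_generation: str  # {"exhaustive", "cmc"}
    J: int = field(init=False)

    def __post_init__(self):
        if not self.shufflings or not self.shufflings[0].is_identity:
            raise ValueError("the first shuffling must be the identity")
        object.__setattr__(self, "J", len(self.shufflings))

    def __iter__(self):
        return iter(self.shufflings)

    def __len__(self):
        return self.J

    def __getitem__(self, j):
        return self.shufflings[j]


def apply_shuffling(sh: Shuffling, A: np.ndarray) -> np.ndarray:
    """Sign-flip then reorder the rows of A (vector or matrix)."""
    A = np.asarray(A)
    if A.shape[0] != sh.N:
        raise ValueError("shuffling and matrix row counts differ")
    s = sh.signs[sh.perm]
    out = A[sh.perm]
    return out * (s[:, None] if A.ndim > 1 else s)


def _row_keys(X_rows, N: int) -> np.ndarray:
    """Integer key per row; identical design rows share a key (exact equality)."""
    if X_rows is None:
        return np.arange(N)
    X = np.asarray(X_rows, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != N:
        raise ValueError("row matrix does not match the number of observations")
    _, inv = np.unique(X, axis=0, return_inverse=True)
    return inv


def _multiset_count(keys) -> int:
    n = len(keys)
    total = math.factorial(n)
    _, counts = np.unique(np.asarray(keys), return_counts=True)
    for c in counts:
        total //= math.factorial(int(c))
    return total


def count_max_shufflings(
    blocks: ExchangeabilityBlocks, X_rows=None, regime: str = "ee"
) -> int:
    """Maximum number of unique shufflings for the given block structure.

    ``X_rows`` are the rows of the interest partition (or the full design for
    strategies that shuffle the whole model); repeated rows make permutations
    synonymous and reduce the count.  Exact Python integers, so arbitrarily
    large counts are fine.
    """
    if regime not in ("ee", "ise", "both"):
        raise ValueError(f"unknown regime {regime!r}")
    N = blocks.N
    keys = _row_keys(X_rows, N)

    def ee_count() -> int:
        if blocks.mode == "unrestricted":
            return _multiset_count(keys)
        if blocks.mode == "within":
            total = 1
            for ix in blocks.block_indices:
                total *= _multiset_count(keys[ix])
            return total
        # whole-block: permute blocks as units; identical blocks are synonymous
        block_keys = [tuple(keys[ix]) for ix in blocks.block_indices]
        return _multiset_count(
            np.unique(block_keys, axis=0, return_inverse=True)[1]
        )

    def ise_count() -> int:
        if blocks.mode == "whole":
            return 2 ** blocks.n_blocks
        return 2**N

    if regime == "ee":
        return ee_count()
    if regime == "ise":
        return ise_count()
    return ee_count() * ise_count()


# ---------------------------------------------------------------------------
# exhaustive enumeration


def _perms_from_key_sequences(keys: np.ndarray, positions: np.ndarray):
    """Unique index permutations of ``positions`` up to equality of row keys.

    One canonical representative per distinct key reordering: indices with a
    given key are consumed in their original order.
    """
    pools: dict = {}
    for pos in positions:
        pools.setdefault(keys[pos], []).append(pos)
    local_keys = [int(keys[p]) for p in positions]
    out = []
    for seq in multiset_permutations(local_keys):
        counters = {k: 0 for k in pools}
        perm = np.empty(len(positions), dtype=np.intp)
        for i, k in enumerate(seq):
            perm[i] = pools[k][counters[k]]
            counters[k] += 1
        out.append(perm)
    return out


def _exhaustive_perms(blocks: ExchangeabilityBlocks, keys: np.ndarray):
    N = blocks.N
    if blocks.mode == "unrestricted":
        return _perms_from_key_sequences(keys, np.arange(N))
    if blocks.mode == "within":
        per_block = [
            _perms_from_key_sequences(keys, ix) for ix in blocks.block_indices
        ]
        out = []
        for combo in itertools.product(*per_block):
            perm = np.empty(N, dtype=np.intp)
            for ix, local in zip(blocks.block_indices, combo):
                perm[ix] = local
            out.append(perm)
        return out
    # whole-block: permute block identities, preserving within-block order
    bix = blocks.block_indices
    block_keys = np.unique(
        [tuple(keys[ix]) for ix in bix], axis=0, return_inverse=True
    )[1]
    block_orders = _perms_from_key_sequences(block_keys, np.arange(len(bix)))
    out = []
    for order in block_orders:
        perm = np.empty(N, dtype=np.intp)
        for slot, src in enumerate(order):
            perm[bix[slot]] = bix[src]
        out.append(perm)
    return out


def _signs_from_id(ident: int, n_units: int, blocks: ExchangeabilityBlocks):
    """Radix-2 identifier -> sign vector (digit 1 flips the unit)."""
    bits = (ident >> np.arange(n_units)) & 1
    unit_signs = (1 - 2 * bits).astype(np.int8)
    if blocks.mode == "whole":
        signs = np.ones(blocks.N, dtype=np.int8)
        for b, ix in enumerate(blocks.block_indices):
            signs[ix] = unit_signs[b]
        return signs
    return unit_signs


def _exhaustive_signs(blocks: ExchangeabilityBlocks):
    n_units = blocks.n_blocks if blocks.mode == "whole" else blocks.N
    return [_signs_from_id(i, n_units, blocks) for i in range(2**n_units)]


# ---------------------------------------------------------------------------
# conditional Monte Carlo


def _random_perm(blocks: ExchangeabilityBlocks, rng: np.random.Generator):
    N = blocks.N
    if blocks.mode == "unrestricted":
        return rng.permutation(N)
    perm = np.arange(N)
    if blocks.mode == "within":
        for ix in blocks.block_indices:
            perm[ix] = ix[rng.permutation(len(ix))]
        return perm
    bix = blocks.block_indices
    order = rng.permutation(len(bix))
    for slot, src in enumerate(order):
        perm[bix[slot]] = bix[src]
    return perm


def _random_signs(blocks: ExchangeabilityBlocks, rng: np.random.Generator):
    if blocks.mode == "whole":
        unit = rng.choice(np.array([1, -1], dtype=np.int8), size=blocks.n_blocks)
        signs = np.ones(blocks.N, dtype=np.int8)
        for b, ix in enumerate(blocks.block_indices):
            signs[ix] = unit[b]
        return signs
    return rng.choice(np.array([1, -1], dtype=np.int8), size=blocks.N)


def enumerate_shufflings(
    blocks: ExchangeabilityBlocks,
    regime: str = "ee",
    J_max: int = 1000,
    seed=None,
    X_rows=None,
    dedup_cmc: bool = False,
    side: str = "data",
) -> ShufflingSet:
    """Build the set of shufflings: exhaustive if the unique count fits in
    ``J_max``, otherwise identity plus ``J_max - 1`` CMC draws.

    Exhaustive sets are returned in randomised order (identity first), since
    truncating a lexicographic enumeration could bias the test.  With
    ``dedup_cmc`` random draws are rejected until distinct (the cardinality
    is capped at the unique count).

    ``side`` states which side of the model the shufflings will be applied
    to, which matters only for the uniqueness reduction with repeated rows:
    a permutation applied to the *data* is equivalent to its transpose
    applied to the *design*, so the synonymy classes differ by an inverse.
    ``"data"`` (default) dedupes on the pattern of P' X, matching strategies
    that shuffle the (residualised) data; ``"design"`` dedupes on P X for
    strategies that shuffle regressors directly.
    """
    if side not in ("data", "design"):
        raise ValueError(f"unknown side {side!r}")
    if J_max < 1:
        raise ValueError("at least one shuffling (the identity) is required")
    if regime not in ("ee", "ise", "both"):
        raise ValueError(f"unknown regime {regime!r}")
    rng = np.random.default_rng(seed)
    N = blocks.N
    keys = _row_keys(X_rows, N)
    total = count_max_shufflings(blocks, X_rows, regime)
    ident = Shuffling.identity(N)

    if total <= J_max:
        if regime in ("ee", "both"):
            perms = _exhaustive_perms(blocks, keys)
            if side == "data":
                # one representative per distinct P'X instead of P X
                perms = [np.argsort(p) for p in perms]
        else:
            perms = [np.arange(N)]
        if regime in ("ise", "both"):
            signs = _exhaustive_signs(blocks)
        else:
            signs = [np.ones(N, dtype=np.int8)]
        shufflings = [
            Shuffling(perm=p, signs=s) for p, s in itertools.product(perms, signs)
        ]
        # identity first, remainder in random order
        shufflings.sort(key=lambda sh: not sh.is_identity)
        tail = shufflings[1:]
        order = rng.permutation(len(tail))
        shufflings = [shufflings[0]] + [tail[i] for i in order]
        return ShufflingSet(
            shufflings=tuple(shufflings),
            regime=regime,
            method_of_generation="exhaustive",
        )

    draws = [ident]
    seen = {ident.key()}
    target = min(J_max, total) if dedup_cmc else J_max
    attempts = 0
    while len(draws) < target:
        perm = _random_perm(blocks, rng) if regime in ("ee", "both") else np.arange(N)
        signs = (
            _random_signs(blocks, rng)
            if regime in ("ise", "both")
            else np.ones(N, dtype=np.int8)
        )
        sh = Shuffling(perm=perm, signs=signs)
        if dedup_cmc:
            attempts += 1
            if sh.key() in seen:
                if attempts > 100 * target:
                    break
                continue
            seen.add(sh.key())
        draws.append(sh)
    return ShufflingSet(
        shufflings=tuple(draws), regime=regime, method_of_generation="cmc"
    )
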