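"""Balanced incomplete block designs (BIBDs) for best-worst scaling.

A BIBD arranges ``v`` items into ``b`` blocks of size ``k`` so that every
item appears in exactly ``r`` blocks and every unordered pair of items
co-occurs in exactly ``lam`` blocks.  The standard counting identities

    v * r = b * k        and        lam * (v - 1) = r * (k - 1)

tie the five parameters together.  For a best-worst questionnaire the
design guarantees that every outcome is offered equally often and against
every other outcome equally often, so raw best/worst tallies are
comparable across items.

Construction tries a cyclic (difference-set) development first — which
covers the classic ``(v, b, k, r, lam) = (13, 13, 4, 4, 1)`` survey design
and the Fano plane ``(7, 7, 3, 3, 1)`` instantly — and falls back to a
deterministic backtracking search over lexicographically ordered blocks.
Generation involves no randomness; presentation-order shuffling lives in
:func:`build_questionnaire` behind an explicit seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .items import ChoiceItem, default_catalog, generic_catalog, validate_catalog

DEFAULT_NODE_BUDGET = 2_000_000
_MAX_LAMBDA = 30


class DesignSearchError(RuntimeError):
    """No design found within the configured search budget."""


@dataclass(frozen=True)
class BIBDesign:
    """A balanced incomplete block design over items ``0 .. v-1``.

    ``blocks`` is an ordered tuple of ``b`` sorted tuples, each holding
    ``k`` distinct 0-based item indices.  Exported files translate indices
    to stable item-id tokens; positions never leave the process.
    """

    v: int
    b: int
    k: int
    r: int
    lam: int
    blocks: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if len(self.blocks) != self.b:
            raise ValueError(f"expected {self.b} blocks, got {len(self.blocks)}")
        for blk in self.blocks:
            if len(set(blk)) != self.k:
                raise ValueError(f"block {blk} does not hold {self.k} distinct items")
            if any(not (0 <= i < self.v) for i in blk):
                raise ValueError(f"block {blk} references an item outside 0..{self.v - 1}")


@dataclass(frozen=True)
class DesignReport:
    """Outcome of :func:`validate_design`: recounts plus per-invariant verdicts."""

    replication: np.ndarray          # per-item block counts, shape (v,)
    cooccurrence: np.ndarray         # pair counts, shape (v, v), zero diagonal
    replication_ok: bool
    cooccurrence_ok: bool
    identities_ok: bool
    violations: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return self.replication_ok and self.cooccurrence_ok and self.identities_ok


def _count_incidence(v: int, blocks: Sequence[Sequence[int]]) -> tuple[np.ndarray, np.ndarray]:
    rep = np.zeros(v, dtype=int)
    co = np.zeros((v, v), dtype=int)
    for blk in blocks:
        for i in blk:
            rep[i] += 1
        for i, j in itertools.combinations(blk, 2):
            co[i, j] += 1
            co[j, i] += 1
    return rep, co


def validate_design(design: BIBDesign) -> DesignReport:
    """Recount replications and pairwise co-occurrences and check every invariant.

    Invalid designs produce a failing report naming each offending item or
    pair; no exception is raised.
    """
    if not design.blocks:
        raise ValueError("design has no blocks")
    rep, co = _count_incidence(design.v, design.blocks)
    violations: list[str] = []

    rep_ok = True
    for i in range(design.v):
        if rep[i] != design.r:
            rep_ok = False
            kind = "over" if rep[i] > design.r else "under"
            violations.append(
                f"item {i} is {kind}-replicated: appears in {rep[i]} blocks, expected {design.r}"
            )

    co_ok = True
    for i, j in itertools.combinations(range(design.v), 2):
        if co[i, j] != design.lam:
            co_ok = False
            violations.append(
                f"pair ({i},{j}) co-occurs in {co[i, j]} blocks, expected {design.lam}"
            )

    ids_ok = True
    if design.v * design.r != design.b * design.k:
        ids_ok = False
        violations.append("identity v*r = b*k violated")
    if design.lam * (design.v - 1) != design.r * (design.k - 1):
        ids_ok = False
        violations.append("identity lam*(v-1) = r*(k-1) violated")

    return DesignReport(rep, co, rep_ok, co_ok, ids_ok, tuple(violations))


def _cyclic_difference_set(v: int, k: int, lam: int) -> tuple[tuple[int, ...], ...] | None:
    """Search for a (v, k, lam) planar difference set in Z_v; develop it cyclically.

    Yields a symmetric-style design with b = v blocks (r = k).  The base
    block is taken to contain 0; candidates are enumerated in lexicographic
    order so the result is deterministic.
    """
    if k * (k - 1) != lam * (v - 1):
        return None
    for rest in itertools.combinations(range(1, v), k - 1):
        base = (0,) + rest
        diffs = np.zeros(v, dtype=int)
        ok = True
        for x, y in itertools.permutations(base, 2):
            d = (x - y) % v
            diffs[d] += 1
            if diffs[d] > lam:
                ok = False
                break
        if ok and all(diffs[1:] == lam):
            blocks = tuple(
                tuple(sorted((x + shift) % v for x in base)) for shift in range(v)
            )
            return blocks
    return None


def _backtrack_blocks(
    v: int, b: int, k: int, r: int, lam: int, node_budget: int
) -> tuple[tuple[int, ...], ...] | None:
    """Depth-first search for b blocks satisfying the BIBD constraints.

    Blocks are built in nondecreasing lexicographic order (a symmetry cut);
    item replication and pair co-occurrence counters prune the tree.  The
    search is deterministic; ``node_budget`` caps the number of visited
    nodes and exhaustion raises :class:`DesignSearchError`.
    """
    rep = [0] * v
    co = [[0] * v for _ in range(v)]
    blocks: list[tuple[int, ...]] = []
    nodes = 0

    all_blocks = list(itertools.combinations(range(v), k))

    def feasible(blk: tuple[int, ...]) -> bool:
        for i in blk:
            if rep[i] >= r:
                return False
        for i, j in itertools.combinations(blk, 2):
            if co[i][j] >= lam:
                return False
        return True

    def place(blk: tuple[int, ...], sign: int) -> None:
        for i in blk:
            rep[i] += sign
        for i, j in itertools.combinations(blk, 2):
            co[i][j] += sign
            co[j][i] += sign

    def rec(start: int) -> bool:
        nonlocal nodes
        nodes += 1
        if nodes > node_budget:
            raise DesignSearchError(
                f"backtracking search for (v={v}, k={k}, b={b}, r={r}, lam={lam}) "
                f"exceeded the node budget of {node_budget}"
            )
        if len(blocks) == b:
            return all(c == r for c in rep)
        for idx in range(start, len(all_blocks)):
            blk = all_blocks[idx]
            if not feasible(blk):
                continue
            place(blk, +1)
            blocks.append(blk)
            # repeated blocks are allowed when lam > 1, hence start=idx
            if rec(idx):
                return True
            blocks.pop()
            place(blk, -1)
        return False

    if rec(0):
        return tuple(blocks)
    return None


def generate_bibd(v: int, k: int, node_budget: int = DEFAULT_NODE_BUDGET) -> BIBDesign:
    """Construct a BIBD with ``v`` items and block size ``k``, minimizing ``b``.

    Feasible parameter triples are scanned in increasing ``lam`` (hence
    increasing ``b``); for each, a cyclic difference-set construction is
    tried before the general backtracking search.  Deterministic: the same
    ``(v, k)`` always yields the same design.

    Raises
    ------
    ValueError
        If ``k < 2`` or ``k > v``.
    DesignSearchError
        If no design is found within the node budget.
    """
    if k < 2:
        raise ValueError(f"block size k must be at least 2, got {k}")
    if k > v:
        raise ValueError(f"block size k={k} exceeds item count v={v}")

    for lam in range(1, _MAX_LAMBDA + 1):
        num_r = lam * (v - 1)
        if num_r % (k - 1):
            continue
        r = num_r // (k - 1)
        if (v * r) % k:
            continue
        b = v * r // k
        if b < v and k < v:  # Fisher's inequality
            continue
        if k == v:
            # complete block: b copies of the full item set
            return BIBDesign(v, b, k, r, lam, tuple((tuple(range(v)),) * b))
        if b == v:
            blocks = _cyclic_difference_set(v, k, lam)
            if blocks is not None:
                return BIBDesign(v, b, k, r, lam, blocks)
        try:
            found = _backtrack_blocks(v, b, k, r, lam, node_budget)
        except DesignSearchError:
            raise
        if found is not None:
            return BIBDesign(v, b, k, r, lam, found)

    raise DesignSearchError(
        f"no BIBD with v={v}, k={k} found for lam <= {_MAX_LAMBDA} "
        f"within the node budget of {node_budget}"
    )


@dataclass(frozen=True)
class Questionnaire:
    """A presentation layout over a design: shuffled blocks and within-block orders.

    The analysis never depends on the layout — picks are keyed by design
    block index — but a printed questionnaire needs a concrete, reproducible
    ordering.
    """

    design: BIBDesign
    catalog: tuple[ChoiceItem, ...]
    block_order: tuple[int, ...]
    within_block_orders: tuple[tuple[int, ...], ...]
    layout_seed: int

    def __post_init__(self) -> None:
        if len(self.catalog) != self.design.v:
            raise ValueError(
                f"catalog has {len(self.catalog)} items, design expects {self.design.v}"
            )
        validate_catalog(self.catalog)
        if sorted(self.block_order) != list(range(self.design.b)):
            raise ValueError("block_order is not a permutation of block indices")
        for bi, order in zip(self.block_order, self.within_block_orders):
            if sorted(order) != sorted(self.design.blocks[bi]):
                raise ValueError(f"within-block order for block {bi} is not a permutation")

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(item.item_id for item in self.catalog)

    def presented_blocks(self) -> list[tuple[int, tuple[str, ...]]]:
        """(design block index, item ids in presentation order) in survey order."""
        ids = self.item_ids
        return [
            (bi, tuple(ids[i] for i in order))
            for bi, order in zip(self.block_order, self.within_block_orders)
        ]


def build_questionnaire(
    design: BIBDesign,
    layout_seed: int,
    catalog: Sequence[ChoiceItem] | None = None,
) -> Questionnaire:
    """Attach a catalog and a seeded presentation shuffle to a design.

    The default catalog is the packaged 13-outcome list when ``v == 13``,
    otherwise a generic one.  Identical seeds give identical layouts.
    """
    if catalog is None:
        catalog = default_catalog() if design.v == 13 else generic_catalog(design.v)
    rng = np.random.default_rng(layout_seed)
    block_order = tuple(int(i) for i in rng.permutation(design.b))
    within = tuple(
        tuple(int(x) for x in rng.permutation(design.blocks[bi]))
        for bi in block_order
    )
    return Questionnaire(design, tuple(catalog), block_order, within, layout_seed)
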