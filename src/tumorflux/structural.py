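"""Structural analysis: elementary flux modes and minimal cut sets.

Blood metabolites are treated as boundary species (the tumor microenvironment
is an open system), intracellular metabolites are balanced at steady state.
Elementary flux modes (EFMs) are enumerated with the classical tableau /
double-description scheme on the reversibility-split network, in exact
rational arithmetic.  Minimal cut sets (MCSs) for a target reaction are the
minimal hitting sets of the supports of the target-containing EFMs, obtained
by Berge's incremental transversal algorithm.  Deleting a cut-set member
removes both directions of a reversible reaction (enzyme-level semantics).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np

from .network import MetabolicNetwork

__all__ = [
    "FluxMode",
    "CutSet",
    "elementary_flux_modes",
    "minimal_cut_sets",
    "essential_reactions",
    "write_cut_set_report",
]


@dataclass(frozen=True)
class FluxMode:
    """A support-minimal steady-state flux pattern.

    ``coefficients`` maps reaction id to a signed rational flux (negative =
    reverse direction of a reversible reaction); ``support`` is its key set.
    """

    coefficients: tuple[tuple[str, Fraction], ...]

    @property
    def support(self) -> frozenset[str]:
        return frozenset(r for r, _ in self.coefficients)

    def coefficient(self, rxn_id: str) -> Fraction:
        return dict(self.coefficients).get(rxn_id, Fraction(0))


@dataclass(frozen=True)
class CutSet:
    """A minimal set of reactions whose deletion blocks the target."""

    reactions: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.reactions)

    def sorted_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.reactions))


# ---------------------------------------------------------------------------
# EFM enumeration (tableau double description, exact arithmetic)
# ---------------------------------------------------------------------------


def _split_network(net: MetabolicNetwork):
    """Columns of the reversibility-split internal stoichiometric matrix.

    Returns (columns, labels) where each label is (reaction_id, +1|-1).
    Intracellular metabolites only; blood species are boundary.
    """
    S = net.S_m
    cols: list[tuple[Fraction, ...]] = []
    labels: list[tuple[str, int]] = []
    for j, rxn in enumerate(net.reactions):
        col = tuple(Fraction(x).limit_denominator(10**9) for x in S[:, j])
        cols.append(col)
        labels.append((rxn.id, +1))
        if rxn.reversible:
            cols.append(tuple(-c for c in col))
            labels.append((rxn.id, -1))
    return cols, labels


def elementary_flux_modes(net: MetabolicNetwork) -> list[FluxMode]:
    """Complete, duplicate-free EFM set, ordered lexicographically by support."""
    if not net.metabolites:
        raise ValueError("empty network")
    # with no internal metabolites there is nothing to balance: every split
    # reaction direction is its own elementary mode
    n_int = net.S_m.shape[0]
    cols, labels = _split_network(net)
    n = len(cols)

    # tableau rows: (reaction part, remaining metabolite part); start from
    # the identity — each split reaction is its own candidate ray.
    rows: list[tuple[list[Fraction], list[Fraction]]] = []
    for i in range(n):
        r = [Fraction(0)] * n
        r[i] = Fraction(1)
        rows.append((r, list(cols[i])))

    remaining = list(range(n_int))
    while remaining:
        # process the metabolite generating the fewest pair combinations
        def cost(k: int) -> int:
            pos = sum(1 for _, m in rows if m[k] > 0)
            neg = sum(1 for _, m in rows if m[k] < 0)
            return pos * neg

        k = min(remaining, key=cost)
        remaining.remove(k)
        zero = [row for row in rows if row[1][k] == 0]
        pos = [row for row in rows if row[1][k] > 0]
        neg = [row for row in rows if row[1][k] < 0]
        new_rows = list(zero)
        kept_masks = [_support_mask(r[0]) for r in zero]
        candidates = []
        for rp in pos:
            for rn in neg:
                a, b = rp[1][k], -rn[1][k]
                coeffs = [b * x + a * y for x, y in zip(rp[0], rn[0])]
                mets = [b * x + a * y for x, y in zip(rp[1], rn[1])]
                candidates.append((coeffs, mets))
        # elementarity pruning: drop candidates whose support strictly
        # contains another row's support
        cand_masks = [_support_mask(c[0]) for c in candidates]
        all_masks = kept_masks + cand_masks
        for ci, (cand, mask) in enumerate(zip(candidates, cand_masks)):
            minimal = True
            for oi, other in enumerate(all_masks):
                if oi == len(kept_masks) + ci:
                    continue
                if other & mask == other and other != mask:
                    minimal = False
                    break
                if other == mask and oi < len(kept_masks) + ci:
                    minimal = False  # duplicate support; keep first
                    break
            if minimal:
                new_rows.append(_normalize(cand))
        rows = new_rows

    # collapse to signed fluxes on original reactions; drop futile two-cycles
    modes: dict[frozenset, FluxMode] = {}
    for coeffs, _ in rows:
        flux: dict[str, Fraction] = {}
        for val, (rid, sign) in zip(coeffs, labels):
            if val != 0:
                flux[rid] = flux.get(rid, Fraction(0)) + sign * val
        flux = {r: v for r, v in flux.items() if v != 0}
        if not flux:
            continue  # pure futile cycle of a reversible reaction
        key = frozenset(flux.items())
        modes.setdefault(key, FluxMode(tuple(sorted(flux.items()))))
    out = list(modes.values())
    out.sort(key=lambda m: tuple(sorted(m.support)))
    return out


def _support_mask(coeffs: list[Fraction]) -> int:
    mask = 0
    for i, c in enumerate(coeffs):
        if c != 0:
            mask |= 1 << i
    return mask


def _normalize(row):
    coeffs, mets = row
    nz = [abs(c) for c in coeffs if c != 0]
    if nz:
        g = min(nz)
        coeffs = [c / g for c in coeffs]
        mets = [c / g for c in mets]
    return coeffs, mets


# ---------------------------------------------------------------------------
# minimal cut sets (Berge transversal of target-EFM supports)
# ---------------------------------------------------------------------------


def minimal_cut_sets(
    net: MetabolicNetwork,
    target: str,
    efms: list[FluxMode] | None = None,
) -> list[CutSet]:
    """Minimal hitting sets of the supports of target-containing EFMs.

    Returns cut sets sorted by size, then lexicographically.  If the target
    carries no EFM the list is empty (the target is already blocked).
    """
    if target not in net.reaction_ids:
        raise KeyError(f"target reaction {target!r} not in network")
    if efms is None:
        efms = elementary_flux_modes(net)
    supports = sorted(
        {m.support for m in efms if target in m.support}, key=len
    )
    if not supports:
        return []

    # index reactions appearing in any target EFM support
    universe = sorted(set().union(*supports))
    idx = {r: i for i, r in enumerate(universe)}
    masks = [sum(1 << idx[r] for r in s) for s in supports]

    transversals = [0]  # bitmask cut sets; start with the empty set
    for smask in masks:
        hit = [t for t in transversals if t & smask]
        miss = [t for t in transversals if not t & smask]
        if not miss:
            continue
        elements = [1 << idx[r] for r in universe if smask >> idx[r] & 1]
        new = list(hit)
        for t in miss:
            for e in elements:
                cand = t | e
                # minimality: no kept transversal may be a subset
                if any(k & cand == k for k in new):
                    continue
                new.append(cand)
        # candidates added later may supersede earlier ones only by equality,
        # since subsets are filtered on insertion; dedupe defensively
        new = _filter_minimal(new)
        transversals = new

    cuts = [
        CutSet(frozenset(universe[i] for i in range(len(universe)) if t >> i & 1))
        for t in transversals
    ]
    cuts.sort(key=lambda c: (c.size, c.sorted_ids()))
    return cuts


def _filter_minimal(masks: list[int]) -> list[int]:
    masks = sorted(set(masks), key=lambda m: bin(m).count("1"))
    kept: list[int] = []
    for m in masks:
        if not any(k & m == k for k in kept):
            kept.append(m)
    return kept


def essential_reactions(
    net: MetabolicNetwork,
    target: str,
    efms: list[FluxMode] | None = None,
) -> list[str]:
    """Reactions present in every target-supporting EFM (the size-one cut sets)."""
    if target not in net.reaction_ids:
        raise KeyError(f"target reaction {target!r} not in network")
    if efms is None:
        efms = elementary_flux_modes(net)
    supports = [m.support for m in efms if target in m.support]
    if not supports:
        return []
    common = frozenset.intersection(*supports)
    return sorted(common)


def write_cut_set_report(cuts: list[CutSet], path: str | Path) -> None:
    """TSV report: size, semicolon-joined reaction ids, ascending by size."""
    lines = ["size\treaction_ids"]
    for c in sorted(cuts, key=lambda c: (c.size, c.sorted_ids())):
        lines.append(f"{c.size}\t{';'.join(c.sorted_ids())}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
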