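"""Parental haplotype phasing from a handful of haploid gametes.

A diploid individual's two haplotypes at its heterozygous markers are
complementary, and each of its gametes is a mosaic of the two with few
crossovers. The relative phase of two nearby markers can therefore be read off
by majority vote: gametes carrying the same allele at both markers vote for
the "cis" orientation, gametes carrying different alleles vote "trans", and
crossovers between the markers are the minority. Chaining these votes along
the chromosome yields one haplotype (the other is its complement).

Links whose vote margin is zero are never guessed: they split the chromosome
into independently anchored phase blocks. With the default link window of 2
the vote for each link combines the adjacent pair with the two next-nearest
pairs (each weight 1), which resolves almost all ties caused by genotyping
error; ties caused by exactly half of the gametes recombining in the same
interval are information-theoretically unresolvable and always split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._codes import ORIGIN_MISSING
from .genotype_io import GameteSet, MarkerMap

__all__ = ["PhasedChromosome", "PhasedParent", "HaplotypeTrack", "phase_individual", "label_origins"]


def _pair_diff(calls: np.ndarray, lag: int) -> np.ndarray:
    """Signed cis-minus-trans vote counts for marker pairs (i, i+lag)."""
    a, b = calls[:, :-lag], calls[:, lag:]
    both = (a >= 0) & (b >= 0)
    votes = np.where(both, np.where(a == b, 1, -1), 0)
    return votes.sum(axis=0)


def _chain_core(pair_votes, hap_a, block, margins, max_lag, n_anchors):
    """Greedy marker orientation against the last two well-oriented anchors.

    ``pair_votes[l-1, a]`` holds the signed cis-minus-trans votes for the
    marker pair (a, a+l). Each marker is oriented by the combined votes
    relative to the one or two most recently oriented markers (within
    ``max_lag``); conflicting evidence that cancels falls back to the nearest
    anchor alone. A marker whose evidence collapses entirely (typically one
    with several bad calls) is left unoriented and bridged, so it costs one
    masked marker rather than a spurious phase break; the chain only starts a
    fresh, independently anchored block when no anchor is within reach.
    Orientation evidence anchored on decided markers (rather than chained
    link relations) keeps one bad marker from flipping the rest of the arm.
    """
    n = hap_a.shape[0]
    a1 = 0  # most recent oriented marker
    a2 = -1  # second most recent
    cur = 0
    orphans = 0
    for m in range(1, n):
        if m - a1 > max_lag:  # chain broken: new independent block
            cur += 1
            hap_a[m] = 0
            block[m] = cur
            a1, a2 = m, -1
            continue
        v = pair_votes[m - a1 - 1, a1] * (1 - 2 * hap_a[a1])
        if n_anchors >= 2 and a2 >= 0 and m - a2 <= max_lag:
            v += pair_votes[m - a2 - 1, a2] * (1 - 2 * hap_a[a2])
        if v == 0:  # cancelling conflict: nearest anchor alone decides
            v = pair_votes[m - a1 - 1, a1] * (1 - 2 * hap_a[a1])
        margins[m - 1] = v if v >= 0 else -v
        if v > 0:
            hap_a[m] = 0
        elif v < 0:
            hap_a[m] = 1
        else:  # no evidence: leave unoriented, bridge to the next marker
            hap_a[m] = 0
            block[m] = -1
            orphans += 1
            continue
        block[m] = block[a1]
        a2, a1 = a1, m
    if orphans > 0:  # each unoriented marker becomes its own phase block
        for m in range(n):
            if block[m] == -1:
                cur += 1
                block[m] = cur


try:  # the chain is sequential; numba removes the interpreter overhead
    from numba import njit

    _chain_core = njit(cache=True)(_chain_core)
except ImportError:  # pragma: no cover - numba is an optional accelerator
    pass


def _phase_chain(calls: np.ndarray, link_window: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orient a marker chain by majority vote.

    Returns (hapA alleles, per-link margins, per-marker block ids). Each phase
    block is anchored with allele A at its first marker; block ids are not
    necessarily increasing along the chromosome (unoriented markers get
    singleton blocks numbered last).
    """
    n_markers = calls.shape[1]
    if n_markers == 1:
        return np.zeros(1, np.int8), np.zeros(0, np.int64), np.zeros(1, np.int64)
    max_lag = 1 if link_window < 2 else min(3, n_markers - 1)
    votes = np.zeros((max_lag, n_markers), dtype=np.int64)
    for lag in range(1, max_lag + 1):
        votes[lag - 1, : n_markers - lag] = _pair_diff(calls, lag)
    hap_a = np.zeros(n_markers, np.int64)
    block = np.zeros(n_markers, np.int64)
    margins = np.zeros(n_markers - 1, np.int64)
    _chain_core(votes, hap_a, block, margins, max_lag, 1 if link_window < 2 else 2)
    return hap_a.astype(np.int8), margins, block


@dataclass
class PhasedChromosome:
    marker_ids: np.ndarray
    rel_positions: np.ndarray
    hap_a: np.ndarray  # allele of haplotype A at each marker
    margins: np.ndarray  # vote margin per adjacent-marker link
    block_ids: np.ndarray

    @property
    def hap_b(self) -> np.ndarray:
        return (1 - self.hap_a).astype(np.int8)

    @property
    def n_blocks(self) -> int:
        return int(self.block_ids.max()) + 1 if len(self.block_ids) else 0

    @property
    def unresolved_links(self) -> np.ndarray:
        """Links where no evidence oriented the next marker (block boundaries)."""
        return np.flatnonzero(np.diff(self.block_ids) != 0)


@dataclass
class PhasedParent:
    individual_id: str
    chromosomes: dict[str, PhasedChromosome] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)  # chromosomes with < 2 markers

    @property
    def n_unresolved_links(self) -> int:
        return sum(len(pc.unresolved_links) for pc in self.chromosomes.values())


@dataclass
class HaplotypeTrack:
    """Haplotype-of-origin labels of one gamete along each chromosome."""

    nucleus_id: str
    origins: dict[str, np.ndarray]  # chrom -> (m,) int8 in {A=0, B=1, missing=-1}
    rel_positions: dict[str, np.ndarray]


def phase_individual(
    gametes: GameteSet, marker_map: MarkerMap, link_window: int = 2
) -> PhasedParent:
    """Phase one individual's informative markers from its gametes.

    Requires at least three gametes; chromosomes with fewer than two
    informative markers are skipped with a warning.
    """
    if gametes.n_nuclei < 3:
        raise ValueError(
            f"{gametes.individual_id}: phasing needs >= 3 gametes, got {gametes.n_nuclei}"
        )
    if link_window not in (1, 2):
        raise ValueError("link_window must be 1 or 2")
    chrom_of = marker_map.marker_chrom
    rel_of = marker_map.marker_rel
    parent = PhasedParent(individual_id=gametes.individual_id)
    marker_arr = np.asarray(gametes.marker_ids)
    chroms = np.asarray([chrom_of[m] for m in marker_arr])
    for chrom in marker_map.chromosomes:
        sel = np.flatnonzero(chroms == chrom)
        if len(sel) == 0:
            continue
        if len(sel) < 2:
            parent.skipped.append(chrom)
            warnings.warn(f"{gametes.individual_id}/{chrom}: < 2 informative markers, skipped")
            continue
        calls = gametes.calls[:, sel]
        hap_a, margins, blocks = _phase_chain(calls, link_window)
        parent.chromosomes[chrom] = PhasedChromosome(
            marker_ids=marker_arr[sel],
            rel_positions=np.asarray([rel_of[m] for m in marker_arr[sel]], dtype=float),
            hap_a=hap_a,
            margins=margins,
            block_ids=blocks,
        )
        if len(margins) > 0 and len(np.unique(blocks)) == len(blocks):
            warnings.warn(f"{gametes.individual_id}/{chrom}: all links unresolved (unphased)")
    return parent


def _block_mask(pc: PhasedChromosome, window_fraction: float) -> np.ndarray:
    """Markers in phase blocks too short to anchor a window are masked.

    Blocks spanning at least one window length keep their labels; if no block
    does, only the longest block is kept.
    """
    if pc.n_blocks <= 1:
        return np.ones(len(pc.hap_a), dtype=bool)
    spans = np.zeros(pc.n_blocks)
    for b in range(pc.n_blocks):
        pos = pc.rel_positions[pc.block_ids == b]
        spans[b] = pos.max() - pos.min()
    keep = spans >= window_fraction
    if not keep.any():
        keep[np.argmax(spans)] = True
    return keep[pc.block_ids]


def label_origins(
    gametes: GameteSet, parent: PhasedParent, window_fraction: float = 0.10
) -> list[HaplotypeTrack]:
    """Map each gamete call to its parental haplotype of origin (A or B)."""
    marker_pos = {m: j for j, m in enumerate(gametes.marker_ids)}
    tracks = [
        HaplotypeTrack(nucleus_id=n, origins={}, rel_positions={}) for n in gametes.nuclei_ids
    ]
    for chrom, pc in parent.chromosomes.items():
        try:
            cols = np.asarray([marker_pos[m] for m in pc.marker_ids])
        except KeyError as exc:
            raise ValueError(f"marker {exc} phased but absent from gamete set") from exc
        calls = gametes.calls[:, cols]
        origins = np.where(calls < 0, ORIGIN_MISSING, (calls != pc.hap_a[None, :]).astype(np.int8))
        origins = origins.astype(np.int8)
        keep = _block_mask(pc, window_fraction)
        origins[:, ~keep] = ORIGIN_MISSING
        for g, tr in enumerate(tracks):
            tr.origins[chrom] = origins[g]
            tr.rel_positions[chrom] = pc.rel_positions
    return tracks
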