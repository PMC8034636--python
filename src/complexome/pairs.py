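"""Co-complex and background pair derivation by matrix expansion.

The unordered protein pair is the currency of every functional-standard
comparison: an n-member complex is matrix-expanded into its n(n-1)/2 member
pairs, and the union of these over a dataset forms its co-complex pairs.
Background pairs are pairs of proteins that each occur somewhere in the
dataset but never together in a single complex; by construction the two sets
are disjoint. Pairs are deduplicated across complexes (a pair shared by three
complexes counts once) and self-pairs are ignored.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

from .io import ComplexDataset, IdMapping

__all__ = [
    "Pair",
    "pair",
    "PairSet",
    "cocomplex_pairs",
    "background_pairs",
    "restrict_to_tested",
    "map_pairs",
    "read_pairs_tsv",
    "write_pairs_tsv",
]

Pair = tuple[str, str]


def pair(a: str, b: str) -> Pair:
    """Canonical unordered pair: lexicographically sorted, self-pairs rejected."""
    if a == b:
        raise ValueError(f"self-pair {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class PairSet:
    """A labelled set of canonical protein pairs."""

    label: str
    pairs: set[Pair] = field(default_factory=set)

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair {a!r} in {self.label}")
            if a > b:
                raise ValueError(f"non-canonical pair {(a, b)!r} in {self.label}")

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, p: Pair) -> bool:
        return p in self.pairs

    def __iter__(self):
        return iter(self.pairs)

    def proteins(self) -> frozenset[str]:
        return frozenset(p for pr in self.pairs for p in pr)


def cocomplex_pairs(ds: ComplexDataset, min_size: int = 2) -> PairSet:
    """Matrix-expand every complex into unordered member pairs and take the union.

    Complexes with fewer than ``min_size`` unique proteins contribute nothing
    (a homomer can never produce a pair). The dataset must already be fully
    expanded to protein sets.
    """
    out: set[Pair] = set()
    for rec in ds.records:
        prots = rec.protein_members
        if len(prots) < min_size:
            continue
        out.update(combinations(sorted(prots), 2))
    return PairSet(f"{ds.dataset_name}:cocomplex", out)


def background_pairs(ds: ComplexDataset) -> PairSet:
    """Pairs of proteins present only in *different* complexes of the dataset.

    The universe is intra-dataset (proteins appearing in >= 1 complex), not
    proteome-wide: all pairs over the dataset's proteins minus the co-complex
    pairs. Disjoint from :func:`cocomplex_pairs` by construction.
    """
    proteins = sorted(ds.proteins())
    co = cocomplex_pairs(ds).pairs
    out = {p for p in combinations(proteins, 2) if p not in co}
    return PairSet(f"{ds.dataset_name}:background", out)


def restrict_to_tested(
    pairs: PairSet, tested: set[Pair] | set[str] | PairSet
) -> tuple[PairSet, float]:
    """Filter a pair set to a tested universe and report the retained fraction.

    ``tested`` may be a set of canonical pairs (a pair is kept iff itself
    tested) or a set of proteins (a pair is kept iff both endpoints are in the
    universe). The coverage fraction is NaN with a warning for an empty input
    set.
    """
    if isinstance(tested, PairSet):
        tested = tested.pairs
    if tested and isinstance(next(iter(tested)), str):
        kept = {p for p in pairs.pairs if p[0] in tested and p[1] in tested}
    else:
        kept = pairs.pairs & set(tested)  # type: ignore[arg-type]
    if not pairs.pairs:
        warnings.warn(f"{pairs.label}: empty pair set, coverage undefined")
        return PairSet(pairs.label + ":tested", set()), math.nan
    return PairSet(pairs.label + ":tested", kept), len(kept) / len(pairs.pairs)


def map_pairs(pairs: PairSet, mapping: IdMapping, drop_unmapped: bool = False) -> PairSet:
    """Translate pairs through a one-to-many identifier mapping.

    Used to carry UniProt-level co-complex pairs into ORF space before
    comparison with genetic-interaction screens. A pair whose endpoints map to
    several targets expands to every cross-combination; combinations that
    collapse to a self-pair are dropped.
    """
    out: set[Pair] = set()
    for a, b in pairs.pairs:
        ta = mapping.get(a, frozenset() if drop_unmapped else frozenset((a,)))
        tb = mapping.get(b, frozenset() if drop_unmapped else frozenset((b,)))
        for x in ta:
            for y in tb:
                if x != y:
                    out.add(pair(x, y))
    return PairSet(pairs.label + ":mapped", out)


def read_pairs_tsv(path, label: str | None = None) -> PairSet:
    """Read a 2-column pair TSV (``#`` comments skipped); pairs canonicalised."""
    out: set[Pair] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            out.add(pair(cols[0].strip(), cols[1].strip()))
    return PairSet(label or str(path), out)


def write_pairs_tsv(pairs: PairSet, path, header: bool = True) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write("# protein_a\tprotein_b\n")
        for a, b in sorted(pairs.pairs):
            fh.write(f"{a}\t{b}\n")
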