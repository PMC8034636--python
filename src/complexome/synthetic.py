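"""Synthetic complexomes and functional standards with known ground truth.

Every pipeline stage is testable without downloads: this module generates
complex datasets with a realistic size law (most complexes small, a short
heavy tail of large paralog-rich assemblies), protein reuse with a
preferential-attachment tail of multi-complex proteins, optional paralog sets
and subcomplex references; derived second datasets with controlled overlap
(identical / one-subunit-perturbed / novel complexes); functional standards
with planted co-complex enrichment (each co-complex pair enters a standard
with probability ``p_co``, each background pair with ``p_bg``); and
intra-complex contact graphs with class-separated profile similarities.

All generators are deterministic given a seed, and every emitted file
round-trips through the package's own readers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .io import ComplexDataset, ComplexRecord, Member
from .pairs import Pair, PairSet, background_pairs, cocomplex_pairs, pair

__all__ = [
    "SizeLaw",
    "OverlapSpec",
    "StandardSpec",
    "ContactSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_complexome",
    "derive_overlapping_dataset",
    "plant_standard",
    "generate_standard",
    "generate_contacts_and_similarities",
    "write_standard_files",
    "write_gi_screens",
    "write_coexpression_scores",
    "write_localizations",
    "write_annotations_and_ontology",
    "write_similarity_table",
]


@dataclass
class SizeLaw:
    """Complex-size distribution: shifted geometric body plus a uniform tail.

    Defaults put the median of sizes >= 3 at 4 and the mean near 7, echoing
    curated yeast complexomes where most complexes have 10 or fewer subunits
    and a few paralog-expanded assemblies (ribosomal subunits) are much
    larger. ``histogram`` overrides the law with an empirical size histogram.
    """

    kind: str = "geometric"
    p: float = 0.3  # body: size = 1 + Geometric(p)
    homomer_fraction: float = 0.02
    tail_fraction: float = 0.05
    tail_range: tuple[int, int] = (20, 60)
    min_size: int = 1
    histogram: dict[int, int] | None = None

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "empirical":
            if not self.histogram:
                raise ValueError("empirical size law requires a histogram")
            sizes = np.repeat(
                list(self.histogram.keys()), list(self.histogram.values())
            )
            return rng.choice(sizes, size=n, replace=True)
        u = rng.random(n)
        sizes = 1 + rng.geometric(self.p, size=n)
        lo, hi = self.tail_range
        tail = rng.integers(lo, hi + 1, size=n)
        sizes = np.where(u < self.tail_fraction, tail, sizes)
        sizes = np.where(
            (u >= self.tail_fraction) & (u < self.tail_fraction + self.homomer_fraction),
            1,
            sizes,
        )
        return np.maximum(sizes, self.min_size)


@dataclass
class OverlapSpec:
    """Composition of a derived dataset relative to its source.

    Fractions of the derived dataset's complexes that are identical copies,
    one-subunit-perturbed copies (one member swapped for a fresh protein) and
    entirely novel complexes over a fresh protein pool. Must sum to 1.
    """

    fraction_identical: float = 0.5
    fraction_swap: float = 0.3
    fraction_novel: float = 0.2

    def __post_init__(self) -> None:
        total = self.fraction_identical + self.fraction_swap + self.fraction_novel
        if abs(total - 1.0) > 1e-9:
            raise ValueError("overlap fractions must sum to 1")


@dataclass
class StandardSpec:
    """Planted functional-standard structure.

    ``p_co``/``p_bg`` are the probabilities that a co-complex or background
    pair belongs to the standard; ``coverage`` the fraction of pairs with
    functional data at all. Defaults mirror the genetic-interaction overlap
    observed for curated yeast complexes: ~30% of tested co-complex pairs
    interacting negatively vs ~6.8% of background pairs (a 4.4-fold
    enrichment), with ~52% of pairs covered by the screens.
    """

    p_co: float = 0.30
    p_bg: float = 0.068
    coverage: float = 0.52
    n_cocomplex: int | None = None  # subsample caps; None = use all pairs
    n_background: int | None = None
    max_screens: int = 3  # GI dialect: screens per tested pair in 1..max
    damp_fraction: float = 0.2  # GI dialect: extra DAmP rows
    coexpression_cutoff: float = 1.0

    def __post_init__(self) -> None:
        for v in (self.p_co, self.p_bg, self.coverage):
            if not 0 <= v <= 1:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class ContactSpec:
    """Intra-complex contact topology and class-separated similarity offsets."""

    density: float = 0.3  # probability of each extra (non-tree) edge
    offset_direct: float = 0.30
    offset_indirect: float = 0.15
    offset_background: float = 0.0
    noise_sd: float = 0.05
    n_alleles: int = 2
    allele_noise_sd: float = 0.02


@dataclass
class SyntheticConfig:
    """Study conditions for a full synthetic complexome."""

    n_proteins: int = 1500
    n_complexes: int = 500
    size_law: SizeLaw = field(default_factory=SizeLaw)
    reuse_alpha: float = 1.0  # preferential-attachment weight increment
    paralog_set_count: int = 0
    paralog_set_size: int = 2
    subcomplex_fraction: float = 0.0
    small_molecule_fraction: float = 0.05
    overlap: OverlapSpec = field(default_factory=OverlapSpec)
    standard: StandardSpec = field(default_factory=StandardSpec)
    contacts: ContactSpec = field(default_factory=ContactSpec)
    seed: int = 0


@dataclass
class SyntheticTruth:
    """Ground truth accompanying generated data."""

    sizes: list[int] = field(default_factory=list)
    paralog_sets: list[frozenset[str]] = field(default_factory=list)
    subcomplex_refs: dict[str, str] = field(default_factory=dict)
    overlap_labels: dict[str, str] = field(default_factory=dict)
    standard_pairs: set[Pair] = field(default_factory=set)
    tested_pairs: set[Pair] = field(default_factory=set)
    p_co: float | None = None
    p_bg: float | None = None
    contact_classes: dict[Pair, str] = field(default_factory=dict)
    gene_similarity: dict[Pair, float] = field(default_factory=dict)


def _protein_ids(n: int, prefix: str = "P") -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(n)]


def generate_complexome(cfg: SyntheticConfig) -> tuple[ComplexDataset, SyntheticTruth]:
    """Draw a complex dataset under the configured study conditions.

    Complex sizes follow the configured law; members are sampled with a
    preferential-attachment weight (``reuse_alpha``) so a small tail of
    multi-complex proteins exists while most proteins occur in one complex.
    Protein sets are kept distinct across complexes. Optionally a fraction of
    complexes reference an earlier complex as a subcomplex member, paralog
    sets are declared over sampled members, and some complexes carry a
    small-molecule (ChEBI) member that protein-membership computations must
    ignore. Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    proteins = np.array(_protein_ids(cfg.n_proteins))
    weights = np.ones(cfg.n_proteins)
    sizes = cfg.size_law.sample(cfg.n_complexes, rng)
    if sizes.max() > cfg.n_proteins:
        raise ValueError(
            f"infeasible config: complex size {int(sizes.max())} exceeds "
            f"{cfg.n_proteins} proteins"
        )
    truth = SyntheticTruth(sizes=[int(s) for s in sizes])
    records: list[ComplexRecord] = []
    seen_sets: set[frozenset[str]] = set()
    for i, s in enumerate(sizes):
        for _ in range(50):
            idx = rng.choice(
                cfg.n_proteins, size=int(s), replace=False, p=weights / weights.sum()
            )
            members = frozenset(proteins[idx])
            if members not in seen_sets:
                break
        else:
            raise ValueError("infeasible config: cannot draw distinct complexes")
        seen_sets.add(members)
        weights[idx] += cfg.reuse_alpha
        member_list = [Member(p, "protein") for p in sorted(members)]
        if rng.random() < cfg.small_molecule_fraction:
            member_list.append(Member(f"CHEBI:{10000 + i}", "small_molecule"))
        records.append(ComplexRecord(f"CPX-{i + 1}", member_list))

    # subcomplex references: later complexes absorb an earlier one
    if cfg.subcomplex_fraction > 0:
        for i in range(1, cfg.n_complexes):
            if rng.random() < cfg.subcomplex_fraction:
                j = int(rng.integers(0, i))
                rec = records[i]
                ref = records[j].complex_id
                rec.members.append(Member(ref, "complex"))
                truth.subcomplex_refs[rec.complex_id] = ref

    paralog_sets: list[frozenset[str]] = []
    if cfg.paralog_set_count:
        used = sorted(set().union(*(r.protein_members for r in records)))
        picked = rng.choice(
            len(used),
            size=min(cfg.paralog_set_count * cfg.paralog_set_size, len(used)),
            replace=False,
        )
        for k in range(cfg.paralog_set_count):
            chunk = picked[k * cfg.paralog_set_size : (k + 1) * cfg.paralog_set_size]
            if len(chunk) == cfg.paralog_set_size:
                paralog_sets.append(frozenset(used[int(c)] for c in chunk))
    truth.paralog_sets = paralog_sets
    ds = ComplexDataset("synthetic", records, paralog_sets)
    return ds, truth


def derive_overlapping_dataset(
    ds: ComplexDataset, spec: OverlapSpec, seed: int
) -> tuple[ComplexDataset, dict[str, str]]:
    """Derive a second dataset with controlled overlap structure.

    Exact counts (not per-complex coin flips): after a seeded shuffle, the
    first ``fraction_identical`` of complexes are copied verbatim, the next
    ``fraction_swap`` have one member swapped for a fresh protein (Jaccard
    index (s-1)/(s+1) against the original), and the rest are replaced by
    novel complexes over a disjoint protein pool (Jaccard 0 against
    everything). Returns the derived dataset and per-derived-complex truth
    labels (``identical`` / ``swapped`` / ``novel``).
    """
    rng = np.random.default_rng(seed)
    n = len(ds.records)
    order = rng.permutation(n)
    n_ident = round(spec.fraction_identical * n)
    n_swap = round(spec.fraction_swap * n)
    labels: dict[str, str] = {}
    records: list[ComplexRecord] = []
    fresh = 0
    for rank, i in enumerate(order):
        src = ds.records[int(i)]
        prots = sorted(src.protein_members)
        if rank < n_ident:
            cid = f"D-{src.complex_id}"
            records.append(
                ComplexRecord(cid, [Member(p, "protein") for p in prots])
            )
            labels[cid] = "identical"
        elif rank < n_ident + n_swap:
            out = int(rng.integers(0, len(prots)))
            swapped = [p for k, p in enumerate(prots) if k != out]
            swapped.append(f"S{fresh:05d}")
            fresh += 1
            cid = f"D-{src.complex_id}"
            records.append(
                ComplexRecord(cid, [Member(p, "protein") for p in sorted(swapped)])
            )
            labels[cid] = "swapped"
        else:
            size = len(prots)
            novel = [f"N{fresh + k:05d}" for k in range(size)]
            fresh += size
            cid = f"NOV-{rank}"
            records.append(
                ComplexRecord(cid, [Member(p, "protein") for p in novel])
            )
            labels[cid] = "novel"
    return ComplexDataset(ds.dataset_name + ":derived", records), labels


# --------------------------------------------------------------------------
# Planted functional standards
# --------------------------------------------------------------------------


def plant_standard(
    cocomplex: PairSet,
    background: PairSet,
    spec: StandardSpec,
    seed: int,
) -> tuple[PairSet, set[Pair], SyntheticTruth]:
    """Plant a functional standard over given pair universes.

    Optionally subsamples the two groups to ``n_cocomplex``/``n_background``
    pairs, marks each pair tested with probability ``coverage``, and puts each
    tested or untested pair into the standard with probability ``p_co``
    (co-complex) or ``p_bg`` (background). Membership is independent of
    tested status, as in a screen whose coverage is unrelated to biology.

    Returns the standard, the tested universe, and the truth object.
    """
    rng = np.random.default_rng(seed)

    def subsample(ps: PairSet, n: int | None) -> list[Pair]:
        pairs = sorted(ps.pairs)
        if n is None or n >= len(pairs):
            return pairs
        idx = rng.choice(len(pairs), size=n, replace=False)
        return [pairs[int(i)] for i in idx]

    co = subsample(cocomplex, spec.n_cocomplex)
    bg = subsample(background, spec.n_background)
    standard: set[Pair] = set()
    tested: set[Pair] = set()
    for group, p_in in ((co, spec.p_co), (bg, spec.p_bg)):
        flags_in = rng.random(len(group)) < p_in
        flags_tested = rng.random(len(group)) < spec.coverage
        for p, fin, ft in zip(group, flags_in, flags_tested):
            if fin:
                standard.add(p)
            if ft:
                tested.add(p)
    truth = SyntheticTruth(
        standard_pairs=set(standard),
        tested_pairs=set(tested),
        p_co=spec.p_co,
        p_bg=spec.p_bg,
    )
    return PairSet("planted", standard), tested, truth


def generate_standard(
    ds: ComplexDataset, spec: StandardSpec, seed: int
) -> tuple[PairSet, set[Pair], SyntheticTruth]:
    """Plant a standard over a dataset's co-complex and background pairs."""
    co = cocomplex_pairs(ds)
    bg = background_pairs(ds)
    return plant_standard(co, bg, spec, seed)


# --------------------------------------------------------------------------
# Dialect emitters (everything round-trips through the package's readers)
# --------------------------------------------------------------------------


def write_gi_screens(
    standard: PairSet,
    tested: set[Pair],
    path,
    spec: StandardSpec,
    seed: int,
    sign: str = "negative",
) -> None:
    """Emit a GI screen table whose consensus calls equal the planted standard.

    Each tested pair gets 1..``max_screens`` screens; planted pairs report
    ``sign`` in a majority of them, others report ``none``. A fraction of
    pairs receive an extra DAmP row with the *opposite* call, which must not
    change the consensus once DAmP rows are dropped.
    """
    rng = np.random.default_rng(seed)
    rows: list[str] = []
    for a, b in sorted(tested):
        k = int(rng.integers(1, spec.max_screens + 1))
        planted = (a, b) in standard.pairs
        n_hit = (k + 1) // 2 + int(rng.integers(0, k - (k + 1) // 2 + 1)) if planted else 0
        for s in range(k):
            outcome = sign if s < n_hit else "none"
            pert = "deletion" if rng.random() < 0.7 else "temperature_sensitive"
            rows.append(f"{a}\t{b}\t{pert}\t{outcome}")
        if rng.random() < spec.damp_fraction:
            outcome = "none" if planted else sign
            rows.append(f"{a}\t{b}\tdamp\t{outcome}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# orf_a\torf_b\tperturbation\toutcome\n")
        fh.write("\n".join(rows) + "\n")


def write_coexpression_scores(
    standard: PairSet, tested: set[Pair], path, spec: StandardSpec, seed: int
) -> None:
    """Emit per-pair co-expression scores straddling the cutoff.

    Planted pairs score strictly above the cutoff, others at or below it
    (a few exactly at the cutoff, exercising the strict inequality).
    """
    rng = np.random.default_rng(seed)
    cut = spec.coexpression_cutoff
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# protein_a\tprotein_b\tscore\n")
        for a, b in sorted(tested):
            if (a, b) in standard.pairs:
                score = cut + 0.01 + 4.0 * rng.random()
            elif rng.random() < 0.05:
                score = cut  # boundary: not co-expressed
            else:
                score = cut * rng.random()
            fh.write(f"{a}\t{b}\t{score:.6f}\n")


def write_localizations(
    standard: PairSet, proteins: set[str], path
) -> None:
    """Emit compartment assignments inducing exactly the planted pair set.

    Every protein gets a private home compartment (so it is annotated and its
    pairs enter the tested universe); each planted pair additionally shares a
    pair-private compartment. Two proteins then share a compartment iff their
    pair was planted.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# protein\tcompartment\n")
        for p in sorted(proteins):
            fh.write(f"{p}\thome_{p}\n")
        for k, (a, b) in enumerate(sorted(standard.pairs)):
            fh.write(f"{a}\tcmp_{k:06d}\n")
            fh.write(f"{b}\tcmp_{k:06d}\n")


def write_annotations_and_ontology(
    standard: PairSet,
    proteins: set[str],
    ann_path,
    ont_path,
    namespace: str = "biological_process",
) -> None:
    """Emit a toy ontology plus annotations inducing the planted pair set.

    The ontology is a small DAG with a root, mid-level terms and a diamond
    motif; each protein gets a private leaf term (annotated once, hence
    surviving any frequency filter and keeping the protein in the universe)
    and each planted pair a pair-private leaf shared by its two proteins.
    All leaves attach under mid-level terms so up-propagation and the
    frequent-term filter are exercised: the root and mid terms are annotated
    to (nearly) everything and must be filtered out.
    """
    mids = ["GO:MID1", "GO:MID2"]
    with open(ont_path, "w", encoding="utf-8") as fh:
        fh.write("# child\tparent\tnamespace\n")
        fh.write(f"GO:ROOT\t\t{namespace}\n")
        for m in mids:
            fh.write(f"{m}\tGO:ROOT\t{namespace}\n")
        # diamond: GO:DIA under both mid terms
        fh.write(f"GO:DIA\tGO:MID1\t{namespace}\n")
        fh.write(f"GO:DIA\tGO:MID2\t{namespace}\n")
        for i, p in enumerate(sorted(proteins)):
            fh.write(f"GO:L{i:06d}\t{mids[i % 2]}\t{namespace}\n")
        for k in range(len(standard.pairs)):
            fh.write(f"GO:S{k:06d}\tGO:DIA\t{namespace}\n")
    with open(ann_path, "w", encoding="utf-8") as fh:
        fh.write("# entity\tterm\tnamespace\n")
        for i, p in enumerate(sorted(proteins)):
            fh.write(f"{p}\tGO:L{i:06d}\t{namespace}\n")
        for k, (a, b) in enumerate(sorted(standard.pairs)):
            fh.write(f"{a}\tGO:S{k:06d}\t{namespace}\n")
            fh.write(f"{b}\tGO:S{k:06d}\t{namespace}\n")


def write_standard_files(
    standard: PairSet, tested: set[Pair], proteins: set[str], outdir, spec: StandardSpec, seed: int
) -> dict[str, str]:
    """Emit one file set per functional-standard dialect into ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "gi_screens": os.path.join(outdir, "gi_screens.tsv"),
        "coexpression": os.path.join(outdir, "coexpression.tsv"),
        "localizations": os.path.join(outdir, "localizations.tsv"),
        "annotations": os.path.join(outdir, "annotations.tsv"),
        "ontology": os.path.join(outdir, "ontology_edges.tsv"),
    }
    write_gi_screens(standard, tested, paths["gi_screens"], spec, seed)
    write_coexpression_scores(standard, tested, paths["coexpression"], spec, seed + 1)
    write_localizations(standard, proteins, paths["localizations"])
    write_annotations_and_ontology(
        standard, proteins, paths["annotations"], paths["ontology"]
    )
    return paths


# --------------------------------------------------------------------------
# Contacts and profile similarities
# --------------------------------------------------------------------------


def generate_contacts_and_similarities(
    ds: ComplexDataset, spec: ContactSpec, seed: int
) -> tuple[ComplexDataset, dict[Pair, float], SyntheticTruth]:
    """Attach contact graphs to complexes and draw class-separated similarities.

    Each complex of size >= 3 receives a connected contact graph (a random
    spanning tree plus each remaining edge with probability ``density``).
    Gene-pair similarities are drawn from class-specific normals: direct
    contacts around ``offset_direct``, same-complex non-contacts around
    ``offset_indirect``, cross-complex pairs around ``offset_background``.
    Returns a new dataset with contacts, the gene-level similarity map and
    the truth (class per pair, exact gene similarities).
    """
    rng = np.random.default_rng(seed)
    records: list[ComplexRecord] = []
    truth = SyntheticTruth()
    for rec in ds.records:
        prots = sorted(rec.protein_members)
        contacts: set[frozenset[str]] = set()
        if len(prots) >= 3:
            order = rng.permutation(len(prots))
            for k in range(1, len(prots)):
                j = int(rng.integers(0, k))  # random spanning tree
                contacts.add(frozenset((prots[int(order[k])], prots[int(order[j])])))
            for i in range(len(prots)):
                for j in range(i + 1, len(prots)):
                    e = frozenset((prots[i], prots[j]))
                    if e not in contacts and rng.random() < spec.density:
                        contacts.add(e)
        records.append(
            ComplexRecord(
                rec.complex_id,
                list(rec.members),
                name=rec.name,
                contacts=contacts,
                annotations=set(rec.annotations),
            )
        )
    out = ComplexDataset(ds.dataset_name, records, list(ds.paralog_sets))

    # classes are defined over the contact-informative subset, as in the
    # downstream analysis: dimers and contact-less complexes contribute nothing
    with_contacts = [rec for rec in records if rec.contacts]
    sub = ComplexDataset(ds.dataset_name + ":contacts", with_contacts)
    direct: set[Pair] = set()
    for rec in with_contacts:
        for c in rec.contacts:
            direct.add(pair(*sorted(c)))
    co = cocomplex_pairs(sub).pairs
    indirect = co - direct
    bg = background_pairs(sub).pairs
    sims: dict[Pair, float] = {}
    for cls, pairs_, offset in (
        ("direct", direct, spec.offset_direct),
        ("indirect", indirect, spec.offset_indirect),
        ("background", bg, spec.offset_background),
    ):
        for p in sorted(pairs_):
            sims[p] = float(offset + rng.normal(0.0, spec.noise_sd))
            truth.contact_classes[p] = cls
    truth.gene_similarity = dict(sims)
    return out, sims, truth


def write_similarity_table(
    sims: dict[Pair, float], path, spec: ContactSpec, seed: int
) -> None:
    """Emit allele-level similarity rows (``GENE-allele`` tags) whose
    per-gene-pair means equal the given gene-level similarities."""
    rng = np.random.default_rng(seed)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# allele_a\tallele_b\tsimilarity\n")
        for (a, b), s in sorted(sims.items()):
            k = spec.n_alleles
            noise = rng.normal(0.0, spec.allele_noise_sd, size=k)
            noise -= noise.mean()  # allele mean stays exactly s
            for idx in range(k):
                fh.write(f"{a}-{idx + 1}\t{b}-{idx + 1}\t{s + noise[idx]:.8f}\n")
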