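"""Reading, normalising and expanding protein-complex datasets.

A complex dataset is a named collection of complexes, each with typed
members (protein, complex, RNA, small molecule) and optional stoichiometry.
Comparisons downstream are always based on unique *protein* identifiers:
stoichiometry is parsed and stored but never enters membership computations,
and non-protein members (nucleic acids, small molecules) are retained on the
record but excluded from protein membership.

Two on-disk dialects are supported:

* ``complextab`` -- the Complex Portal tab-delimited export. Only the columns
  needed are consumed (complex accession, recommended name, participants with
  stoichiometry, GO annotations); unknown columns are ignored.
* ``simple_tsv`` -- a minimal 2-column table: ``complex_id<TAB>members``, with
  members pipe-separated and an optional ``(stoichiometry)`` suffix.

Both are UTF-8, tab-delimited; lines starting with ``#`` are comments, except
a ``#``-prefixed header row in ComplexTab files.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "Member",
    "ComplexRecord",
    "ComplexDataset",
    "IdMapping",
    "ComplexTableError",
    "MEMBER_TYPES",
    "read_complex_table",
    "write_simple_tsv",
    "read_paralog_sets",
    "read_id_mapping",
    "read_contacts",
    "expand_subcomplexes",
    "expand_paralog_sets",
    "map_identifiers",
]

MEMBER_TYPES = ("protein", "complex", "rna", "small_molecule")

# Identifier-namespace prefixes used to infer member types. The dataset's own
# complex accessions are additionally treated as complex-type references.
DEFAULT_TYPE_PREFIXES: dict[str, str] = {
    "CPX-": "complex",
    "CHEBI:": "small_molecule",
    "URS": "rna",
}


class ComplexTableError(ValueError):
    """Raised for malformed complex tables (bad participant tokens, duplicate ids)."""


@dataclass(frozen=True)
class Member:
    """One participant of a complex.

    ``stoichiometry`` is a non-negative integer, with 0 meaning unknown (the
    ComplexTab convention). It is carried through but never used when protein
    memberships are compared.
    """

    member_id: str
    member_type: str = "protein"
    stoichiometry: int = 0

    def __post_init__(self) -> None:
        if self.member_type not in MEMBER_TYPES:
            raise ValueError(f"unknown member type {self.member_type!r}")
        if self.stoichiometry < 0:
            raise ValueError("stoichiometry must be non-negative")


@dataclass
class ComplexRecord:
    """A named complex with typed members, optional contacts and GO annotations.

    ``contacts`` holds unordered pairs of member ids that are in direct
    physical contact within the complex; pairs must reference members of the
    record and self-pairs are rejected.
    """

    complex_id: str
    members: list[Member]
    name: str = ""
    contacts: set[frozenset[str]] = field(default_factory=set)
    annotations: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.complex_id:
            raise ValueError("complex_id must be nonempty")
        if not self.members:
            raise ValueError(f"complex {self.complex_id}: member list is empty")
        ids = {m.member_id for m in self.members}
        for pair in self.contacts:
            if len(pair) != 2:
                raise ValueError(f"complex {self.complex_id}: self-pair in contacts")
            if not pair <= ids:
                raise ValueError(
                    f"complex {self.complex_id}: contact pair {sorted(pair)} "
                    "references non-members"
                )

    @property
    def protein_members(self) -> frozenset[str]:
        """Unique protein identifiers of this record (non-proteins excluded)."""
        return frozenset(m.member_id for m in self.members if m.member_type == "protein")

    @property
    def size(self) -> int:
        """Number of unique protein members."""
        return len(self.protein_members)

    def has_complex_members(self) -> bool:
        return any(m.member_type == "complex" for m in self.members)


@dataclass
class ComplexDataset:
    """A named collection of complexes plus paralog sets declared on proteins."""

    dataset_name: str
    records: list[ComplexRecord]
    paralog_sets: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.complex_id in seen:
                raise ComplexTableError(f"duplicate complex_id {rec.complex_id!r}")
            seen.add(rec.complex_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, complex_id: str) -> ComplexRecord:
        for rec in self.records:
            if rec.complex_id == complex_id:
                return rec
        raise KeyError(complex_id)

    def proteins(self) -> frozenset[str]:
        """Union of protein memberships over all records."""
        out: set[str] = set()
        for rec in self.records:
            out |= rec.protein_members
        return frozenset(out)

    def protein_sets(self, min_size: int = 1) -> dict[str, frozenset[str]]:
        """complex_id -> protein membership, for complexes of size >= min_size."""
        return {
            rec.complex_id: rec.protein_members
            for rec in self.records
            if rec.size >= min_size
        }


IdMapping = dict[str, frozenset[str]]


# --------------------------------------------------------------------------
# Parsing
# --------------------------------------------------------------------------

_PARTICIPANT_RE = re.compile(r"^(?P<id>[^()|\t]+?)(?:\((?P<stoich>\d+)\))?$")


def _infer_member_type(
    member_id: str,
    type_prefixes: dict[str, str],
    dataset_complex_ids: set[str] | None = None,
) -> str:
    if dataset_complex_ids and member_id in dataset_complex_ids:
        return "complex"
    for prefix, mtype in type_prefixes.items():
        if member_id.startswith(prefix):
            return mtype
    return "protein"


def _parse_participant(token: str, lineno: int) -> tuple[str, int]:
    token = token.strip()
    m = _PARTICIPANT_RE.match(token)
    if m is None or not m.group("id").strip():
        raise ComplexTableError(f"line {lineno}: malformed participant token {token!r}")
    stoich = int(m.group("stoich")) if m.group("stoich") is not None else 0
    return m.group("id").strip(), stoich


def _iter_tsv_rows(path) -> list[tuple[int, list[str]]]:
    rows: list[tuple[int, list[str]]] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            rows.append((lineno, line.split("\t")))
    return rows


def _find_column(header: list[str], *needles: str) -> int | None:
    lowered = [h.lower().lstrip("#").strip() for h in header]
    for needle in needles:
        for i, h in enumerate(lowered):
            if needle in h:
                return i
    return None


def read_complex_table(
    path,
    dialect: str = "simple_tsv",
    dataset_name: str | None = None,
    type_prefixes: dict[str, str] | None = None,
) -> ComplexDataset:
    """Parse a complex table into a :class:`ComplexDataset`.

    Parameters
    ----------
    path
        TSV file in one of the supported dialects.
    dialect
        ``"complextab"`` (Complex Portal export) or ``"simple_tsv"``
        (``complex_id<TAB>A(2)|B|CHEBI:29105(1)``).
    dataset_name
        Defaults to the file stem.
    type_prefixes
        Mapping of identifier prefix to member type, overriding the defaults
        (``CPX-`` complex, ``CHEBI:`` small molecule, ``URS`` RNA). Identifiers
        matching another complex id of the same file are always typed
        ``complex`` regardless of prefix.
    """
    if dialect not in ("complextab", "simple_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    prefixes = DEFAULT_TYPE_PREFIXES if type_prefixes is None else type_prefixes
    name = dataset_name if dataset_name is not None else _stem(path)
    rows = _iter_tsv_rows(path)
    if not rows:
        raise ComplexTableError(f"{path}: empty file")

    if dialect == "complextab":
        lineno0, header = rows[0]
        id_col = _find_column(header, "complex ac", "complex_id", "complex id")
        part_col = _find_column(
            header, "stoichiometry) of molecules", "participants", "members"
        )
        if id_col is None or part_col is None:
            raise ComplexTableError(
                f"{path}: header row must identify complex-id and participant columns"
            )
        name_col = _find_column(header, "recommended name", "name")
        go_col = _find_column(header, "go annotations", "go_terms")
        body = rows[1:]
    else:
        id_col, part_col, name_col, go_col = 0, 1, None, None
        body = [(ln, r) for ln, r in rows if not r[0].startswith("#")]

    # first pass: collect ids so internal references can be typed as complexes
    raw: list[tuple[int, list[str]]] = []
    ids: set[str] = set()
    for lineno, row in body:
        if len(row) <= max(id_col, part_col):
            raise ComplexTableError(f"line {lineno}: expected >= {part_col + 1} columns")
        cid = row[id_col].strip()
        if not cid:
            raise ComplexTableError(f"line {lineno}: empty complex id")
        if cid in ids:
            raise ComplexTableError(f"line {lineno}: duplicate complex_id {cid!r}")
        ids.add(cid)
        raw.append((lineno, row))

    records: list[ComplexRecord] = []
    for lineno, row in raw:
        cid = row[id_col].strip()
        members = []
        for token in row[part_col].split("|"):
            mid, stoich = _parse_participant(token, lineno)
            mtype = _infer_member_type(mid, prefixes, ids)
            members.append(Member(mid, mtype, stoich))
        annotations: set[str] = set()
        if go_col is not None and len(row) > go_col and row[go_col].strip():
            for tok in row[go_col].split("|"):
                annotations.add(tok.split("(")[0].strip())
        rec_name = row[name_col].strip() if name_col is not None and len(row) > name_col else ""
        records.append(
            ComplexRecord(cid, members, name=rec_name, annotations=annotations)
        )
    return ComplexDataset(name, records)


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


def write_simple_tsv(ds: ComplexDataset, path) -> None:
    """Serialise a dataset in the 2-column simple dialect (round-trippable)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# complex_id\tmembers\n")
        for rec in ds.records:
            toks = []
            for m in sorted(rec.members, key=lambda m: m.member_id):
                tok = m.member_id
                if m.stoichiometry:
                    tok += f"({m.stoichiometry})"
                toks.append(tok)
            fh.write(f"{rec.complex_id}\t{'|'.join(toks)}\n")


def read_paralog_sets(path) -> list[frozenset[str]]:
    """Read paralog sets from a 2-column TSV (set_id, protein_id)."""
    groups: dict[str, set[str]] = {}
    for lineno, row in _iter_tsv_rows(path):
        if row[0].startswith("#"):
            continue
        if len(row) < 2:
            raise ComplexTableError(f"line {lineno}: expected 2 columns")
        groups.setdefault(row[0].strip(), set()).add(row[1].strip())
    return [frozenset(g) for g in groups.values()]


def read_id_mapping(path) -> IdMapping:
    """Read a one-to-many identifier mapping from a 2-column TSV (source, target)."""
    mapping: dict[str, set[str]] = {}
    for lineno, row in _iter_tsv_rows(path):
        if row[0].startswith("#"):
            continue
        if len(row) < 2:
            raise ComplexTableError(f"line {lineno}: expected 2 columns")
        mapping.setdefault(row[0].strip(), set()).add(row[1].strip())
    return {k: frozenset(v) for k, v in mapping.items()}


def read_contacts(path) -> dict[str, set[frozenset[str]]]:
    """Read intra-complex contacts from a 3-column TSV (complex_id, member_a, member_b)."""
    contacts: dict[str, set[frozenset[str]]] = {}
    for lineno, row in _iter_tsv_rows(path):
        if row[0].startswith("#"):
            continue
        if len(row) < 3:
            raise ComplexTableError(f"line {lineno}: expected 3 columns")
        a, b = row[1].strip(), row[2].strip()
        if a == b:
            raise ComplexTableError(f"line {lineno}: self-contact {a!r}")
        contacts.setdefault(row[0].strip(), set()).add(frozenset((a, b)))
    return contacts


# --------------------------------------------------------------------------
# Expansion
# --------------------------------------------------------------------------


def expand_subcomplexes(ds: ComplexDataset) -> ComplexDataset:
    """Recursively replace complex-type members by the referenced protein members.

    Complexes that are part of larger assemblies (subcomplexes) are expanded so
    every record carries only non-complex members. Dangling references raise;
    cyclic references raise an error naming the cycle. Idempotent.
    """
    by_id = {rec.complex_id: rec for rec in ds.records}
    cache: dict[str, list[Member]] = {}

    def flatten(cid: str, stack: tuple[str, ...]) -> list[Member]:
        if cid in cache:
            return cache[cid]
        if cid in stack:
            cycle = " -> ".join(stack[stack.index(cid):] + (cid,))
            raise ComplexTableError(f"cyclic subcomplex reference: {cycle}")
        rec = by_id[cid]
        out: list[Member] = []
        seen: set[tuple[str, str]] = set()
        for m in rec.members:
            if m.member_type == "complex":
                if m.member_id not in by_id:
                    raise ComplexTableError(
                        f"complex {cid}: dangling subcomplex reference {m.member_id!r}"
                    )
                for sub in flatten(m.member_id, stack + (cid,)):
                    key = (sub.member_id, sub.member_type)
                    if key not in seen:
                        seen.add(key)
                        # stoichiometry of inherited members is unknown
                        out.append(replace(sub, stoichiometry=0))
            else:
                key = (m.member_id, m.member_type)
                if key not in seen:
                    seen.add(key)
                    out.append(m)
        cache[cid] = out
        return out

    records = [
        ComplexRecord(
            rec.complex_id,
            flatten(rec.complex_id, ()),
            name=rec.name,
            contacts=set(rec.contacts),
            annotations=set(rec.annotations),
        )
        for rec in ds.records
    ]
    return ComplexDataset(ds.dataset_name, records, list(ds.paralog_sets))


def expand_paralog_sets(ds: ComplexDataset) -> ComplexDataset:
    """Replace any member belonging to a paralog set by the union of that set.

    Sets of interchangeable paralogous proteins (e.g. duplicated ribosomal
    proteins) are expanded to the full list, so all potential identifiers enter
    the analysis. Membership counts may grow; this over-inflation is a
    documented property of the expansion, not a bug.
    """
    set_of: dict[str, frozenset[str]] = {}
    for pset in ds.paralog_sets:
        for p in pset:
            set_of[p] = pset

    records = []
    for rec in ds.records:
        members: list[Member] = []
        seen: set[tuple[str, str]] = set()
        for m in rec.members:
            if m.member_type == "protein" and m.member_id in set_of:
                for pid in sorted(set_of[m.member_id]):
                    key = (pid, "protein")
                    if key not in seen:
                        seen.add(key)
                        members.append(Member(pid, "protein", 0))
            else:
                key = (m.member_id, m.member_type)
                if key not in seen:
                    seen.add(key)
                    members.append(m)
        records.append(
            ComplexRecord(
                rec.complex_id,
                members,
                name=rec.name,
                contacts=set(rec.contacts),
                annotations=set(rec.annotations),
            )
        )
    return ComplexDataset(ds.dataset_name, records, list(ds.paralog_sets))


def map_identifiers(
    ds: ComplexDataset,
    mapping: IdMapping,
    drop_unmapped: bool = False,
) -> tuple[ComplexDataset, list[str]]:
    """Translate protein identifiers through a one-to-many mapping.

    Each protein member id is replaced by *all* of its mapped targets, so
    ambiguous mappings expand the membership. Unmapped identifiers are reported
    and, by default, retained verbatim (set ``drop_unmapped=True`` to remove
    them instead).

    Returns the mapped dataset and the sorted list of unmapped identifiers.
    """
    unmapped: set[str] = set()
    records = []
    for rec in ds.records:
        members: list[Member] = []
        seen: set[tuple[str, str]] = set()

        def add(mid: str, mtype: str, stoich: int) -> None:
            key = (mid, mtype)
            if key not in seen:
                seen.add(key)
                members.append(Member(mid, mtype, stoich))

        for m in rec.members:
            if m.member_type != "protein":
                add(m.member_id, m.member_type, m.stoichiometry)
            elif m.member_id in mapping:
                for target in sorted(mapping[m.member_id]):
                    add(target, "protein", m.stoichiometry)
            else:
                unmapped.add(m.member_id)
                if not drop_unmapped:
                    add(m.member_id, "protein", m.stoichiometry)
        if not members:
            raise ComplexTableError(
                f"complex {rec.complex_id}: all members unmapped and dropped"
            )

        def targets(mid: str) -> frozenset[str]:
            if mid in mapping:
                return mapping[mid]
            return frozenset() if drop_unmapped else frozenset((mid,))

        contacts: set[frozenset[str]] = set()
        for pair in rec.contacts:
            a, b = tuple(pair)
            for ta in targets(a):
                for tb in targets(b):
                    if ta != tb:
                        contacts.add(frozenset((ta, tb)))
        records.append(
            ComplexRecord(
                rec.complex_id,
                members,
                name=rec.name,
                contacts=contacts,
                annotations=set(rec.annotations),
            )
        )
    report = sorted(unmapped)
    if report:
        warnings.warn(f"{len(report)} identifiers unmapped in {ds.dataset_name}")
    return ComplexDataset(ds.dataset_name, records, list(ds.paralog_sets)), report
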