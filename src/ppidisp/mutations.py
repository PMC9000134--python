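"""Mutation set processing: filtering, flank verification, interface mapping.

Common variants are kept at minor allele frequency >= 1% (inclusive),
deduplicated by (protein, position) keeping the first record in input
order, and removed wherever a disease mutation occupies the same
position. Flank verification requires the transcript window of up to 10
residues on each side of the mutation (shorter near sequence ends) to
occur in the reference protein sequence at the identical position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ppidisp.interactome import Interactome, InvalidInputError

MUTATION_CLASSES = ("common", "disease")


@dataclass
class MutationRecord:
    """One missense variant and its per-PPI binding-energy changes."""

    protein_id: str
    position: int
    wt_residue: str
    mut_residue: str
    mclass: str
    maf: float | None = None
    effects: dict[str, float] = field(default_factory=dict)
    pathogenic_assertion: bool = True  # pre-filter flag for disease records
    record_id: str | None = None  # explicit unique id (cohorts may repeat variants)

    def __post_init__(self) -> None:
        if self.mclass not in MUTATION_CLASSES:
            raise InvalidInputError(f"unknown mutation class {self.mclass!r}")
        if self.wt_residue == self.mut_residue:
            raise InvalidInputError("wt_residue must differ from mut_residue")
        if self.position < 1:
            raise InvalidInputError("position must be 1-based")
        if self.mclass == "common":
            if self.maf is None:
                raise InvalidInputError("common mutations require a MAF")
            if not (0.0 <= self.maf <= 1.0):
                raise InvalidInputError("MAF must lie in [0, 1]")

    @property
    def key(self) -> tuple[str, int]:
        return (self.protein_id, self.position)

    @property
    def id(self) -> str:
        if self.record_id is not None:
            return self.record_id
        return f"{self.protein_id}:{self.wt_residue}{self.position}{self.mut_residue}"


@dataclass
class TranscriptRecord:
    """A transcript-derived protein sequence carrying a mutation position."""

    protein_id: str
    transcript_sequence: str
    mutation_position: int

    def __post_init__(self) -> None:
        if not (1 <= self.mutation_position <= len(self.transcript_sequence)):
            raise InvalidInputError("mutation position outside transcript bounds")


def verify_flank(
    transcript: TranscriptRecord,
    uniprot_sequence: str,
    flank_length: int = 10,
) -> bool:
    """Check the mutation's flanking window against the reference sequence.

    The window spans min(flank_length, available) residues on each side
    of the mutation plus the wild-type residue itself, and must occur in
    ``uniprot_sequence`` at the identical position as on the transcript.
    """
    pos = transcript.mutation_position  # 1-based
    seq = transcript.transcript_sequence
    left = min(flank_length, pos - 1)
    right = min(flank_length, len(seq) - pos)
    window = seq[pos - 1 - left : pos + right]
    start = pos - 1 - left  # 0-based start of window on both sequences
    if start + len(window) > len(uniprot_sequence):
        return False
    return uniprot_sequence[start : start + len(window)] == window


def _dedupe_by_position(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    seen: set[tuple[str, int]] = set()
    kept = []
    for rec in records:
        if rec.key in seen:
            continue
        seen.add(rec.key)
        kept.append(rec)
    return kept


def filter_mutation_sets(
    common: Sequence[MutationRecord],
    disease: Sequence[MutationRecord],
    maf_min: float = 0.01,
) -> tuple[list[MutationRecord], list[MutationRecord]]:
    """Filter the common and disease cohorts.

    Disease records are deduplicated by (protein, position); records
    whose ``pathogenic_assertion`` flag is false are dropped first.
    Common records are kept at maf >= maf_min, deduplicated, then any
    record sharing a (protein, position) with a kept disease record is
    removed. First record in input order wins on duplicates.
    """
    disease_kept = _dedupe_by_position(
        [r for r in disease if r.pathogenic_assertion]
    )
    disease_keys = {r.key for r in disease_kept}
    common_kept = [
        r
        for r in _dedupe_by_position(
            [r for r in common if r.maf is not None and r.maf >= maf_min]
        )
        if r.key not in disease_keys
    ]
    return common_kept, disease_kept


def locate_interfacial(
    mutations: Sequence[MutationRecord],
    interactome: Interactome,
) -> dict[str, list[str]]:
    """Map each mutation to the PPIs whose interface contains its position.

    Returns mutation id -> list of PPI ids (possibly empty) in stable
    interactome order. A PPI is listed iff the mutation's protein is a
    partner and the mutation position lies in that partner's interface
    set for the PPI. Mutations on proteins absent from the interactome
    get empty lists.
    """
    by_protein: dict[str, list] = {}
    for ppi in interactome.ppis:
        for pid in set(ppi.partners()):
            by_protein.setdefault(pid, []).append(ppi)
    out: dict[str, list[str]] = {}
    for mut in mutations:
        hits = []
        for ppi in by_protein.get(mut.protein_id, ()):
            if mut.position in ppi.interface_of(mut.protein_id):
                hits.append(ppi.id)
        out[mut.id] = hits
    return out


# ---------------------------------------------------------------------------
# I/O: mutation table and ddG-effect table (FoldX BuildModel summary shape)
# ---------------------------------------------------------------------------

_MUT_HEADER = "record_id\tprotein_id\tposition\twt\tmut\tclass\tmaf\n"
_DDG_HEADER = "mutation_id\tprotein_id\tposition\tmut\tppi_id\tddg\n"


def write_mutations_tsv(records: Iterable[MutationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_MUT_HEADER)
        for rec in records:
            maf = "" if rec.maf is None else repr(float(rec.maf))
            rid = rec.record_id or ""
            fh.write(
                f"{rid}\t{rec.protein_id}\t{rec.position}\t{rec.wt_residue}\t"
                f"{rec.mut_residue}\t{rec.mclass}\t{maf}\n"
            )


def read_mutations_tsv(path: str | Path) -> list[MutationRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("record_id"):
            raise InvalidInputError(f"{path}: unexpected mutation table header")
        for line in fh:
            if not line.strip():
                continue
            rid, pid, pos, wt, mut, mclass, maf = line.rstrip("\n").split("\t")
            records.append(
                MutationRecord(
                    protein_id=pid,
                    position=int(pos),
                    wt_residue=wt,
                    mut_residue=mut,
                    mclass=mclass,
                    maf=float(maf) if maf else None,
                    record_id=rid or None,
                )
            )
    return records


def write_effects_tsv(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write per-(mutation, PPI) ddG rows (FoldX summary shape plus mutation id)."""
    with open(path, "w") as fh:
        fh.write(_DDG_HEADER)
        for rec in records:
            for ppi_id, ddg in rec.effects.items():
                fh.write(
                    f"{rec.id}\t{rec.protein_id}\t{rec.position}\t{rec.mut_residue}\t"
                    f"{ppi_id}\t{ddg!r}\n"
                )


def attach_effects_tsv(records: Sequence[MutationRecord], path: str | Path) -> None:
    """Attach ddG effects from a TSV onto matching mutation records in place."""
    index: dict[str, MutationRecord] = {r.id: r for r in records}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("mutation_id"):
            raise InvalidInputError(f"{path}: unexpected effects table header")
        for line in fh:
            if not line.strip():
                continue
            mid, _pid, _pos, _mut, ppi_id, ddg = line.rstrip("\n").split("\t")
            rec = index.get(mid)
            if rec is not None:
                rec.effects[ppi_id] = float(ddg)
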