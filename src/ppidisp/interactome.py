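"""Structural interactome data model and interface geometry.

Interface residues are defined by inter-chain atomic contacts: a residue
is interfacial when its minimum all-atom Euclidean distance to the other
chain is within a cutoff (default 5.0 angstrom, inclusive). Template
annotation requires each partner to map at least a configurable fraction
(default 0.5, inclusive) of a chain's interface residues through a
sequence alignment. Mutual exclusivity between two PPIs of a shared
protein is declared when their interfaces on that protein overlap by at
least half of the smaller interface (configurable).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Exclusivity-count bins used in classification and reporting.
EXCLUSIVITY_BINS = ("0", "1-4", ">=5")


class InvalidInputError(ValueError):
    """Raised when a structural or network input violates its contract."""


@dataclass(frozen=True)
class Protein:
    """A protein with an opaque identifier and its amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidInputError(f"protein {self.id!r} has empty sequence")
        bad = set(self.sequence) - _AA_ALPHABET
        if bad:
            raise InvalidInputError(
                f"protein {self.id!r} has non-standard residues {sorted(bad)}"
            )


@dataclass
class ChainStructure:
    """One chain of a structure: ordered residues with atom coordinates.

    ``residues`` maps strictly increasing 1-based residue positions to
    (n_atoms, 3) coordinate arrays in angstrom.
    """

    chain_id: str
    residues: list[tuple[int, np.ndarray]]

    def __post_init__(self) -> None:
        positions = [pos for pos, _ in self.residues]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise InvalidInputError(
                f"chain {self.chain_id!r}: residue positions must strictly increase"
            )
        coerced = []
        for pos, atoms in self.residues:
            arr = np.asarray(atoms, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] == 0:
                raise InvalidInputError(
                    f"chain {self.chain_id!r} residue {pos}: needs >=1 atom with xyz"
                )
            coerced.append((int(pos), arr))
        self.residues = coerced

    @property
    def positions(self) -> list[int]:
        return [pos for pos, _ in self.residues]

    def all_atoms(self) -> tuple[np.ndarray, np.ndarray]:
        """Stacked (n_atoms, 3) coordinates and the residue position of each atom."""
        coords = np.concatenate([atoms for _, atoms in self.residues], axis=0)
        owner = np.concatenate(
            [np.full(len(atoms), pos, dtype=int) for pos, atoms in self.residues]
        )
        return coords, owner


@dataclass(frozen=True)
class AlignmentRecord:
    """A pairwise protein-to-chain alignment (BLAST-style record).

    ``residue_map`` maps chain residue positions to protein sequence
    positions and must be injective.
    """

    query_protein_id: str
    chain_id: str
    e_value: float
    residue_map: Mapping[int, int]

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise InvalidInputError("alignment e_value must be >= 0")
        values = list(self.residue_map.values())
        if len(set(values)) != len(values):
            raise InvalidInputError("alignment residue_map must be injective")


@dataclass
class PPIRecord:
    """One protein-protein interaction with per-partner interface sets."""

    partner_a: str
    partner_b: str
    interface_a: frozenset[int] = frozenset()
    interface_b: frozenset[int] = frozenset()
    delta_g: float | None = None
    template: tuple[str, tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        self.interface_a = frozenset(int(p) for p in self.interface_a)
        self.interface_b = frozenset(int(p) for p in self.interface_b)

    @property
    def id(self) -> str:
        return f"{self.partner_a}--{self.partner_b}"

    @property
    def is_homodimer(self) -> bool:
        return self.partner_a == self.partner_b

    def partners(self) -> tuple[str, str]:
        return (self.partner_a, self.partner_b)

    def interface_of(self, protein_id: str) -> frozenset[int]:
        """Union of this PPI's interface positions on ``protein_id``.

        For homodimers both chain roles contribute.
        """
        out: frozenset[int] = frozenset()
        if protein_id == self.partner_a:
            out |= self.interface_a
        if protein_id == self.partner_b:
            out |= self.interface_b
        return out


@dataclass
class Interactome:
    """A named collection of proteins and PPIs.

    Duplicate unordered partner pairs are collapsed, first occurrence
    wins. Every PPI partner must resolve to a protein, and interface
    positions must fall within the partner sequence.
    """

    proteins: dict[str, Protein]
    ppis: list[PPIRecord]
    name: str = "interactome"

    def __init__(
        self,
        proteins: Iterable[Protein] | Mapping[str, Protein],
        ppis: Iterable[PPIRecord],
        name: str = "interactome",
    ) -> None:
        if isinstance(proteins, Mapping):
            self.proteins = dict(proteins)
        else:
            self.proteins = {p.id: p for p in proteins}
        self.name = name
        self.ppis = []
        seen: set[frozenset[str] | tuple[str, str]] = set()
        for ppi in ppis:
            for pid in ppi.partners():
                if pid not in self.proteins:
                    raise InvalidInputError(
                        f"PPI {ppi.id}: partner {pid!r} not in protein set"
                    )
            key = frozenset(ppi.partners()) if not ppi.is_homodimer else (
                ppi.partner_a,
                ppi.partner_a,
            )
            if key in seen:
                continue
            seen.add(key)
            for pid, iface in (
                (ppi.partner_a, ppi.interface_a),
                (ppi.partner_b, ppi.interface_b),
            ):
                n = len(self.proteins[pid].sequence)
                if any(pos < 1 or pos > n for pos in iface):
                    raise InvalidInputError(
                        f"PPI {ppi.id}: interface position out of bounds for {pid!r}"
                    )
            self.ppis.append(ppi)

    def ppis_of(self, protein_id: str) -> list[PPIRecord]:
        return [p for p in self.ppis if protein_id in p.partners()]

    def __len__(self) -> int:
        return len(self.ppis)


def compute_interface(
    chain_a: ChainStructure,
    chain_b: ChainStructure,
    distance_cutoff: float = 5.0,
) -> tuple[set[int], set[int]]:
    """Interface residues of two chains at an inter-atomic distance cutoff.

    A residue of one chain is interfacial iff the minimum Euclidean
    distance between any of its atoms and any atom of the other chain is
    <= ``distance_cutoff`` (inclusive boundary).

    Returns the two interface position sets (chain_a's, chain_b's);
    either both are empty or both are non-empty.
    """
    if distance_cutoff <= 0:
        raise InvalidInputError("distance_cutoff must be > 0")
    if not chain_a.residues or not chain_b.residues:
        raise InvalidInputError("both chains must contain residues with atoms")
    coords_a, owner_a = chain_a.all_atoms()
    coords_b, owner_b = chain_b.all_atoms()
    d = cdist(coords_a, coords_b)
    contact = d <= distance_cutoff
    iface_a = set(owner_a[contact.any(axis=1)].tolist())
    iface_b = set(owner_b[contact.any(axis=0)].tolist())
    return iface_a, iface_b


def _best_alignments(
    alignments: Iterable[AlignmentRecord],
    e_value_cutoff: float = 1e-5,
) -> dict[tuple[str, str], AlignmentRecord]:
    """Filter at the E-value cutoff and keep the smallest-E-value record
    per (protein, chain) pair (stable: first wins on ties)."""
    best: dict[tuple[str, str], AlignmentRecord] = {}
    for rec in alignments:
        if rec.e_value > e_value_cutoff:
            continue
        key = (rec.query_protein_id, rec.chain_id)
        if key not in best or rec.e_value < best[key].e_value:
            best[key] = rec
    return best


def annotate_ppi_template(
    ppi_partners: tuple[Protein, Protein],
    chain_pair_interface: tuple[set[int], set[int]],
    alignments: Iterable[AlignmentRecord],
    chain_pair: tuple[str, str],
    structure_id: str = "",
    coverage_threshold: float = 0.5,
    e_value_cutoff: float = 1e-5,
) -> PPIRecord | None:
    """Annotate a PPI with a template chain pair if interface coverage allows.

    Each partner must align (E-value <= cutoff, best alignment per
    protein/chain pair) to a distinct chain of the pair such that the
    fraction of that chain's interface residues present in the
    alignment's residue map is >= ``coverage_threshold`` (inclusive).
    Interface positions are re-expressed in protein-sequence coordinates.

    Returns a :class:`PPIRecord` carrying the mapped interfaces and the
    template annotation, or ``None`` when no chain assignment satisfies
    the coverage rule.
    """
    prot_a, prot_b = ppi_partners
    iface_1, iface_2 = (set(chain_pair_interface[0]), set(chain_pair_interface[1]))
    chain_1, chain_2 = chain_pair
    best = _best_alignments(alignments, e_value_cutoff)

    def _mapped(protein: Protein, chain_id: str, iface: set[int]):
        rec = best.get((protein.id, chain_id))
        if rec is None:
            return None
        covered = [pos for pos in iface if pos in rec.residue_map]
        frac = len(covered) / len(iface) if iface else 1.0
        if frac < coverage_threshold:
            return None
        mapped = frozenset(rec.residue_map[pos] for pos in covered)
        n = len(protein.sequence)
        if any(p < 1 or p > n for p in mapped):
            raise InvalidInputError(
                f"alignment maps outside sequence bounds of {protein.id!r}"
            )
        return mapped

    # Try both chain assignments; partners must land on distinct chains.
    for (ca, ia), (cb, ib) in (
        ((chain_1, iface_1), (chain_2, iface_2)),
        ((chain_2, iface_2), (chain_1, iface_1)),
    ):
        mapped_a = _mapped(prot_a, ca, ia)
        mapped_b = _mapped(prot_b, cb, ib)
        if mapped_a is not None and mapped_b is not None:
            return PPIRecord(
                partner_a=prot_a.id,
                partner_b=prot_b.id,
                interface_a=mapped_a,
                interface_b=mapped_b,
                template=(structure_id, (ca, cb)),
            )
    return None


def interface_overlap(set1: frozenset[int] | set[int], set2: frozenset[int] | set[int]) -> float:
    """Overlap fraction of the smaller set: |intersection| / min(|s1|, |s2|).

    Empty sets contribute zero overlap.
    """
    if not set1 or not set2:
        return 0.0
    return len(set(set1) & set(set2)) / min(len(set1), len(set2))


def exclusivity_bin(count: int) -> str:
    if count == 0:
        return EXCLUSIVITY_BINS[0]
    if count <= 4:
        return EXCLUSIVITY_BINS[1]
    return EXCLUSIVITY_BINS[2]


def count_mutually_exclusive(
    interactome: Interactome,
    ppi: PPIRecord,
    overlap_threshold: float = 0.5,
) -> tuple[int, str]:
    """Number of PPIs sharing a binding interface with ``ppi`` mutually
    exclusively, and its bin ('0', '1-4', '>=5').

    Another PPI q of either partner p counts when the interfaces of the
    two PPIs on p overlap by >= ``overlap_threshold`` of the smaller
    interface. Each competing PPI is counted once even if it conflicts
    on both partners.
    """
    if not (0.0 < overlap_threshold <= 1.0):
        raise InvalidInputError("overlap_threshold must be in (0, 1]")
    exclusive_ids: set[str] = set()
    for p in set(ppi.partners()):
        mine = ppi.interface_of(p)
        for other in interactome.ppis_of(p):
            if other is ppi or other.id == ppi.id:
                continue
            theirs = other.interface_of(p)
            if interface_overlap(mine, theirs) >= overlap_threshold:
                exclusive_ids.add(other.id)
    count = len(exclusive_ids)
    return count, exclusivity_bin(count)


# ---------------------------------------------------------------------------
# I/O: PDB coordinates, FASTA sequences, interactome TSV
# ---------------------------------------------------------------------------

def read_pdb_chains(path: str | Path) -> dict[str, ChainStructure]:
    """Read ATOM records of the first model of a PDB file, per chain.

    Hetero/solvent records are excluded; all ATOM atoms (including
    hydrogens, if present) are kept.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(Path(path).stem, str(path))
    model = next(structure.get_models())  # first model only
    chains: dict[str, ChainStructure] = {}
    for chain in model:
        residues = []
        for residue in chain:
            hetflag, resseq, _ = residue.get_id()
            if hetflag.strip():  # skip HETATM / waters
                continue
            coords = np.array([atom.coord for atom in residue], dtype=float)
            if len(coords):
                residues.append((int(resseq), coords))
        residues.sort(key=lambda t: t[0])
        if residues:
            chains[chain.id] = ChainStructure(chain_id=chain.id, residues=residues)
    return chains


def read_fasta(path: str | Path) -> dict[str, Protein]:
    from Bio import SeqIO

    return {
        rec.id: Protein(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(proteins: Iterable[Protein], path: str | Path) -> None:
    with open(path, "w") as fh:
        for prot in proteins:
            fh.write(f">{prot.id}\n{prot.sequence}\n")


_TSV_HEADER = "partner_a\tpartner_b\tinterface_a\tinterface_b\tdelta_g\ttemplate\n"


def _fmt_positions(positions: frozenset[int]) -> str:
    return ",".join(str(p) for p in sorted(positions))


def _parse_positions(text: str) -> frozenset[int]:
    text = text.strip()
    if not text:
        return frozenset()
    return frozenset(int(tok) for tok in text.split(","))


def write_interactome_tsv(interactome: Interactome, path: str | Path) -> None:
    """One PPI per row; comma-separated interface positions per partner."""
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER)
        for ppi in interactome.ppis:
            dg = "" if ppi.delta_g is None else repr(float(ppi.delta_g))
            tmpl = ""
            if ppi.template is not None:
                sid, (c1, c2) = ppi.template
                tmpl = f"{sid}:{c1}:{c2}"
            fh.write(
                f"{ppi.partner_a}\t{ppi.partner_b}\t"
                f"{_fmt_positions(ppi.interface_a)}\t{_fmt_positions(ppi.interface_b)}\t"
                f"{dg}\t{tmpl}\n"
            )


def read_interactome_tsv(
    path: str | Path,
    proteins: Mapping[str, Protein],
    name: str = "interactome",
) -> Interactome:
    ppis = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("partner_a"):
            raise InvalidInputError(f"{path}: unexpected interactome header")
        for line in fh:
            if not line.strip():
                continue
            pa, pb, ia, ib, dg, tmpl = line.rstrip("\n").split("\t")
            template = None
            if tmpl:
                sid, c1, c2 = tmpl.split(":")
                template = (sid, (c1, c2))
            ppis.append(
                PPIRecord(
                    partner_a=pa,
                    partner_b=pb,
                    interface_a=_parse_positions(ia),
                    interface_b=_parse_positions(ib),
                    delta_g=float(dg) if dg else None,
                    template=template,
                )
            )
    return Interactome(proteins=proteins, ppis=ppis, name=name)
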