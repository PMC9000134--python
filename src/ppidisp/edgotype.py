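"""Edgotype prediction from interfacial binding-energy changes.

A mutation edgetically disrupts a PPI iff it lies on the interface
mediating that PPI and its ddG exceeds the cutoff (default 0.5 kcal/mol,
strict). A mutation is edgetic if it disrupts at least one PPI and
quasi-wild-type otherwise; mono-edgetic mutations disrupt exactly one.
Quasi-null outcomes are not predicted here: strongly detrimental
mutations are assumed quasi-null downstream and never enter the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ppidisp.classify import PROPERTY_GROUPS, ClassificationLabels
from ppidisp.interactome import InvalidInputError
from ppidisp.mutations import MutationRecord

DDG_CUTOFF_DEFAULT = 0.5
#: Cutoffs used in robustness sweeps alongside the default.
DDG_SWEEP_CUTOFFS = (0.5, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class DisruptionCall:
    """Disruption verdict for one (mutation, PPI) pair."""

    mutation_id: str
    ppi_id: str
    on_interface: bool
    ddg: float | None
    disrupted: bool
    incomplete: bool = False  # interfacial but no ddG available

    def __post_init__(self) -> None:
        if self.disrupted and not (self.on_interface and self.ddg is not None):
            raise InvalidInputError(
                "a disrupted call requires interface location and a ddG value"
            )


@dataclass(frozen=True)
class EdgotypeAssignment:
    """Edgotype of one mutation over its protein's PPIs."""

    mutation_id: str
    n_disrupted: int
    n_ppis_of_protein: int
    label: str  # 'edgetic' | 'quasi_wild_type'
    mono_edgetic: bool


@dataclass
class EdgotypeCounts:
    """Disruption counts for one property row (two mutation classes x two groups)."""

    property_name: str
    group_pair: tuple[str, str]
    common_total: int = 0
    common_disrupt_T: int = 0
    common_disrupt_P: int = 0
    disease_total: int = 0
    disease_disrupt_T: int = 0
    disease_disrupt_P: int = 0

    def __post_init__(self) -> None:
        for cls in ("common", "disease"):
            total = getattr(self, f"{cls}_total")
            for grp in ("T", "P"):
                n = getattr(self, f"{cls}_disrupt_{grp}")
                if n < 0 or n > total:
                    raise InvalidInputError(
                        f"{self.property_name}: {cls} disrupt count {n} "
                        f"inconsistent with total {total}"
                    )


def predict_disruptions(
    mutation: MutationRecord,
    interfacial_ppis: Sequence[str],
    ddg_cutoff: float = DDG_CUTOFF_DEFAULT,
    all_ppis: Sequence[str] | None = None,
) -> list[DisruptionCall]:
    """Disruption calls for one mutation.

    ``interfacial_ppis`` lists the PPIs whose interface contains the
    mutation (from :func:`ppidisp.mutations.locate_interfacial`);
    ``all_ppis`` optionally lists every PPI of the mutation's protein so
    non-interfacial PPIs receive explicit undisrupted calls. Disruption
    requires interface location AND ddg > ddg_cutoff (strict);
    interfacial PPIs lacking a ddG are undisrupted and flagged
    incomplete.
    """
    interfacial = set(interfacial_ppis)
    ppi_ids = list(all_ppis) if all_ppis is not None else list(interfacial_ppis)
    calls = []
    for ppi_id in ppi_ids:
        on_interface = ppi_id in interfacial
        ddg = mutation.effects.get(ppi_id)
        disrupted = bool(on_interface and ddg is not None and ddg > ddg_cutoff)
        calls.append(
            DisruptionCall(
                mutation_id=mutation.id,
                ppi_id=ppi_id,
                on_interface=on_interface,
                ddg=ddg,
                disrupted=disrupted,
                incomplete=on_interface and ddg is None,
            )
        )
    return calls


def assign_edgotype(
    calls: Sequence[DisruptionCall],
    protein_degree: int,
) -> EdgotypeAssignment:
    """Edgotype of a mutation from its complete set of disruption calls."""
    if not calls:
        raise InvalidInputError("assign_edgotype requires at least one call")
    mutation_ids = {c.mutation_id for c in calls}
    if len(mutation_ids) != 1:
        raise InvalidInputError("calls must belong to a single mutation")
    n_disrupted = sum(1 for c in calls if c.disrupted)
    return EdgotypeAssignment(
        mutation_id=next(iter(mutation_ids)),
        n_disrupted=n_disrupted,
        n_ppis_of_protein=protein_degree,
        label="edgetic" if n_disrupted >= 1 else "quasi_wild_type",
        mono_edgetic=n_disrupted == 1,
    )


def tabulate(
    mutations: Sequence[MutationRecord],
    calls_by_mutation: Mapping[str, Sequence[DisruptionCall]],
    labels: Mapping[str, ClassificationLabels],
    property_name: str,
    ppis_by_protein: Mapping[str, Sequence[str]],
    mono_edgetic: bool = False,
) -> EdgotypeCounts:
    """Count, per mutation class, mutations disrupting T- and P-group PPIs.

    A mutation is eligible for the row (enters the class total) iff its
    protein has at least one PPI labeled T or P for ``property_name``;
    unknown-labeled PPIs are ignored throughout. A mutation counts in
    disrupt_T when it disrupts >= 1 T-group PPI (and analogously for P);
    it may count in both groups. With ``mono_edgetic`` a mutation counts
    in a group only when it disrupts exactly one PPI of that group.
    """
    if property_name not in PROPERTY_GROUPS:
        raise InvalidInputError(f"unknown property {property_name!r}")
    counts = EdgotypeCounts(property_name=property_name, group_pair=("T", "P"))

    def group_of(ppi_id: str) -> str | None:
        lab = labels.get(ppi_id)
        return None if lab is None else lab.group_for(property_name)

    for mut in mutations:
        eligible = any(
            group_of(ppi_id) is not None
            for ppi_id in ppis_by_protein.get(mut.protein_id, ())
        )
        if not eligible:
            continue
        cls = mut.mclass
        setattr(counts, f"{cls}_total", getattr(counts, f"{cls}_total") + 1)
        disrupted_by_group: dict[str, int] = {"T": 0, "P": 0}
        for call in calls_by_mutation.get(mut.id, ()):
            if call.disrupted:
                grp = group_of(call.ppi_id)
                if grp is not None:
                    disrupted_by_group[grp] += 1
        for grp, n in disrupted_by_group.items():
            hit = (n == 1) if mono_edgetic else (n >= 1)
            if hit:
                attr = f"{cls}_disrupt_{grp}"
                setattr(counts, attr, getattr(counts, attr) + 1)
    return counts


def sweep_cutoffs(
    mutations: Sequence[MutationRecord],
    interfacial_map: Mapping[str, Sequence[str]],
    labels: Mapping[str, ClassificationLabels],
    property_name: str,
    ppis_by_protein: Mapping[str, Sequence[str]],
    cutoffs: Sequence[float] = DDG_SWEEP_CUTOFFS,
    mono_edgetic: bool = False,
) -> dict[float, EdgotypeCounts]:
    """Tabulated counts at each ddG cutoff (robustness sweep)."""
    out = {}
    for cutoff in cutoffs:
        calls = {
            mut.id: predict_disruptions(mut, interfacial_map.get(mut.id, ()), cutoff)
            for mut in mutations
        }
        out[cutoff] = tabulate(
            mutations, calls, labels, property_name, ppis_by_protein, mono_edgetic
        )
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_COUNTS_FIELDS = (
    "property_name",
    "common_total",
    "common_disrupt_T",
    "common_disrupt_P",
    "disease_total",
    "disease_disrupt_T",
    "disease_disrupt_P",
)


def write_counts_tsv(
    rows: Iterable[EdgotypeCounts], path: str | Path, dataset: str = ""
) -> None:
    """Write count rows in the shape of the published per-property table."""
    with open(path, "w") as fh:
        fh.write("dataset\t" + "\t".join(_COUNTS_FIELDS) + "\n")
        for row in rows:
            cells = [dataset] + [str(getattr(row, f)) for f in _COUNTS_FIELDS]
            fh.write("\t".join(cells) + "\n")


def read_counts_tsv(path: str | Path) -> list[tuple[str, EdgotypeCounts]]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["dataset", "property_name"]:
            raise InvalidInputError(f"{path}: unexpected counts header")
        for line in fh:
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            rec = dict(zip(header, cells))
            rows.append(
                (
                    rec["dataset"],
                    EdgotypeCounts(
                        property_name=rec["property_name"],
                        group_pair=("T", "P"),
                        **{
                            f: int(rec[f])
                            for f in _COUNTS_FIELDS
                            if f != "property_name"
                        },
                    ),
                )
            )
    return rows


def write_edgotypes_tsv(
    assignments: Iterable[EdgotypeAssignment], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("mutation_id\tn_disrupted\tn_ppis_of_protein\tlabel\tmono_edgetic\n")
        for a in assignments:
            fh.write(
                f"{a.mutation_id}\t{a.n_disrupted}\t{a.n_ppis_of_protein}\t"
                f"{a.label}\t{int(a.mono_edgetic)}\n"
            )
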