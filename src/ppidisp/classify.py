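"""Transient/permanent PPI classification.

Eight property families label each PPI:

* strength — weak iff binding free energy dG >= -25 kcal/mol (inclusive);
* temporal — transient iff partner co-expression is below the dataset
  median in a strict majority of time-course experiments;
* spatial (expression and promoter-activity sources) — transient iff
  tissue co-expression is below the dataset median;
* balance over time / over space (two spatial sources) — unbalanced iff
  the mean absolute log10 expression difference exceeds the dataset
  median;
* interface exclusivity — binned count of mutually exclusive PPIs.

All median comparisons are strict: values equal to the threshold fall on
the permanent/balanced side. Majorities require strictly more than half
of the experiments with a defined value; even splits fall to the
permanent/balanced side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ppidisp.interactome import (
    Interactome,
    InvalidInputError,
    PPIRecord,
    count_mutually_exclusive,
)

EXPERIMENT_KINDS = ("time_course", "tissue")

#: Canonical property names and the label values mapped to the
#: transient-like ("T") and permanent-like ("P") groups.
PROPERTY_GROUPS: dict[str, dict[str, str]] = {
    "strength": {"weak": "T", "strong": "P"},
    "temporal": {"transient": "T", "permanent": "P"},
    "spatial_expr": {"transient": "T", "permanent": "P"},
    "spatial_promoter": {"transient": "T", "permanent": "P"},
    "balance_time": {"unbalanced": "T", "balanced": "P"},
    "balance_space_expr": {"unbalanced": "T", "balanced": "P"},
    "balance_space_promoter": {"unbalanced": "T", "balanced": "P"},
    "exclusivity_1_4": {"1-4": "T", "0": "P"},
    "exclusivity_ge5": {">=5": "T", "0": "P"},
}


@dataclass
class ExpressionExperiment:
    """One expression experiment: genes x conditions.

    ``matrix`` maps gene id to an ordered list of expression values
    (NaN marks an undefined value). Time-course experiments require at
    least 5 conditions.
    """

    experiment_id: str
    kind: str
    matrix: dict[str, list[float]]
    condition_labels: list[str]

    def __post_init__(self) -> None:
        if self.kind not in EXPERIMENT_KINDS:
            raise InvalidInputError(f"unknown experiment kind {self.kind!r}")
        n = len(self.condition_labels)
        if self.kind == "time_course" and n < 5:
            raise InvalidInputError(
                f"{self.experiment_id}: time-course experiments need >=5 time points"
            )
        for gene, values in self.matrix.items():
            if len(values) != n:
                raise InvalidInputError(
                    f"{self.experiment_id}: profile length mismatch for {gene!r}"
                )

    def profile(self, gene: str) -> np.ndarray | None:
        vals = self.matrix.get(gene)
        return None if vals is None else np.asarray(vals, dtype=float)


@dataclass(frozen=True)
class CoexpressionRecord:
    """Pearson co-expression of one PPI's partners in one experiment."""

    ppi_id: str
    experiment_id: str
    pearson_r: float | None
    n_shared_conditions: int


@dataclass(frozen=True)
class ImbalanceRecord:
    """Mean absolute log10 expression difference of one PPI's partners."""

    ppi_id: str
    experiment_id: str
    mean_abs_log10_diff: float | None
    n_valid_points: int


@dataclass
class ClassifierConfig:
    """Thresholds for all classifiers.

    ``median_thresholds`` carries one entry per threshold-based property
    (keys of :data:`PROPERTY_GROUPS` minus strength/exclusivity); missing
    entries are derived from the data at classification time.
    """

    dg_weak_cutoff: float = -25.0
    median_thresholds: dict[str, float] = field(default_factory=dict)
    overlap_threshold: float = 0.5
    ddg_cutoff: float = 0.5
    min_shared: int = 5

    def __post_init__(self) -> None:
        for key, val in self.median_thresholds.items():
            if not math.isfinite(val):
                raise InvalidInputError(f"threshold {key!r} must be finite")


@dataclass
class ClassificationLabels:
    """Per-PPI verdicts for the eight transient/permanent properties."""

    ppi_id: str
    strength: str = "unknown"
    temporal: str = "unknown"
    spatial_expr: str = "unknown"
    spatial_promoter: str = "unknown"
    balance_time: str = "unknown"
    balance_space_expr: str = "unknown"
    balance_space_promoter: str = "unknown"
    exclusivity_bin: str = "0"

    def value_for(self, property_name: str) -> str:
        """The label value of this PPI for a canonical property name."""
        if property_name in ("exclusivity_1_4", "exclusivity_ge5"):
            return self.exclusivity_bin
        if property_name not in PROPERTY_GROUPS:
            raise InvalidInputError(f"unknown property {property_name!r}")
        return getattr(self, property_name)

    def group_for(self, property_name: str) -> str | None:
        """'T', 'P', or None (unlabeled for this property)."""
        return PROPERTY_GROUPS[property_name].get(self.value_for(property_name))


def classify_strength(delta_g: float | None, cutoff: float = -25.0) -> str:
    """'weak' iff dG >= cutoff (inclusive), 'strong' below, 'unknown' if absent."""
    if delta_g is None or not math.isfinite(delta_g):
        return "unknown"
    return "weak" if delta_g >= cutoff else "strong"


def pairwise_coexpression(
    experiment: ExpressionExperiment,
    partners: tuple[str, str],
    min_shared: int = 5,
) -> CoexpressionRecord:
    """Sample Pearson correlation of two partner profiles.

    Computed over conditions where both genes have defined (non-NaN)
    values; undefined when fewer than ``min_shared`` shared conditions
    remain or either profile has zero variance, or a gene is absent.
    """
    ppi_id = f"{partners[0]}--{partners[1]}"
    x = experiment.profile(partners[0])
    y = experiment.profile(partners[1])
    if x is None or y is None:
        return CoexpressionRecord(ppi_id, experiment.experiment_id, None, 0)
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < min_shared:
        return CoexpressionRecord(ppi_id, experiment.experiment_id, None, n)
    xv, yv = x[mask], y[mask]
    if np.std(xv) == 0 or np.std(yv) == 0:
        return CoexpressionRecord(ppi_id, experiment.experiment_id, None, n)
    r = float(np.corrcoef(xv, yv)[0, 1])
    return CoexpressionRecord(ppi_id, experiment.experiment_id, r, n)


def classify_temporal(
    records: Sequence[CoexpressionRecord],
    global_median: float,
) -> str:
    """Majority verdict over time-course experiments.

    Per experiment the PPI is transient iff r < global_median (strict);
    overall transient iff transient in strictly more than half of the
    experiments with a defined correlation; 'unknown' when none defined.
    """
    defined = [r.pearson_r for r in records if r.pearson_r is not None]
    if not defined:
        return "unknown"
    n_transient = sum(1 for r in defined if r < global_median)
    return "transient" if n_transient * 2 > len(defined) else "permanent"


def classify_spatial(record: CoexpressionRecord, median_threshold: float) -> str:
    """Single-source verdict: transient iff r < threshold (strict)."""
    if record.pearson_r is None:
        return "unknown"
    return "transient" if record.pearson_r < median_threshold else "permanent"


def abundance_imbalance(
    experiment: ExpressionExperiment,
    partners: tuple[str, str],
) -> ImbalanceRecord:
    """Mean absolute log10 expression difference between partners.

    Conditions where either value is missing or not strictly positive
    are skipped (no pseudocount); undefined when no condition survives.
    """
    ppi_id = f"{partners[0]}--{partners[1]}"
    x = experiment.profile(partners[0])
    y = experiment.profile(partners[1])
    if x is None or y is None:
        return ImbalanceRecord(ppi_id, experiment.experiment_id, None, 0)
    with np.errstate(invalid="ignore"):
        mask = (x > 0) & (y > 0)
    n = int(mask.sum())
    if n == 0:
        return ImbalanceRecord(ppi_id, experiment.experiment_id, None, 0)
    diff = np.abs(np.log10(x[mask]) - np.log10(y[mask]))
    return ImbalanceRecord(ppi_id, experiment.experiment_id, float(diff.mean()), n)


def classify_balance(
    records: Sequence[ImbalanceRecord],
    global_median: float,
    majority_mode: bool = True,
) -> str:
    """'unbalanced' iff the imbalance exceeds the median (strict >).

    With ``majority_mode`` (time-course data) the verdict is taken per
    experiment and aggregated by strict majority over experiments with a
    defined value; otherwise a single record is expected.
    """
    defined = [
        r.mean_abs_log10_diff for r in records if r.mean_abs_log10_diff is not None
    ]
    if not defined:
        return "unknown"
    if not majority_mode and len(defined) != 1:
        raise InvalidInputError("single-record mode expects exactly one defined value")
    n_unbalanced = sum(1 for v in defined if v > global_median)
    return "unbalanced" if n_unbalanced * 2 > len(defined) else "balanced"


def derive_median(values: Iterable[float]) -> float:
    """Sample median after dropping undefined (None/NaN) entries.

    Mean of the middle two for even counts; empty input is an error.
    """
    clean = [v for v in values if v is not None and not math.isnan(v)]
    if not clean:
        raise InvalidInputError("cannot take the median of an empty collection")
    return float(np.median(clean))


# ---------------------------------------------------------------------------
# Full-dataset classification driver
# ---------------------------------------------------------------------------

def classify_all(
    interactome: Interactome,
    experiments: Sequence[ExpressionExperiment],
    config: ClassifierConfig | None = None,
    promoter_experiment_ids: Iterable[str] = (),
) -> dict[str, ClassificationLabels]:
    """Label every PPI under all eight properties.

    Tissue experiments listed in ``promoter_experiment_ids`` are treated
    as the promoter-activity source; remaining tissue experiments as the
    expression source (multiple sources of one kind are pooled when
    deriving medians, and the first defined record per PPI is used for
    single-value verdicts). Median thresholds missing from the config
    are derived from all defined (PPI, experiment) values in the dataset.
    """
    config = config or ClassifierConfig()
    time_exps = [e for e in experiments if e.kind == "time_course"]
    promoter_ids = set(promoter_experiment_ids)
    tissue_expr = [
        e for e in experiments if e.kind == "tissue" and e.experiment_id not in promoter_ids
    ]
    tissue_prom = [
        e for e in experiments if e.kind == "tissue" and e.experiment_id in promoter_ids
    ]

    def coexpr_records(exps):
        return {
            ppi.id: [
                pairwise_coexpression(e, ppi.partners(), config.min_shared)
                for e in exps
            ]
            for ppi in interactome.ppis
        }

    def imbalance_records(exps):
        return {
            ppi.id: [abundance_imbalance(e, ppi.partners()) for e in exps]
            for ppi in interactome.ppis
        }

    time_co = coexpr_records(time_exps)
    expr_co = coexpr_records(tissue_expr)
    prom_co = coexpr_records(tissue_prom)
    time_im = imbalance_records(time_exps)
    expr_im = imbalance_records(tissue_expr)
    prom_im = imbalance_records(tissue_prom)

    def threshold(key: str, pooled_values: list[float]) -> float | None:
        if key in config.median_thresholds:
            return config.median_thresholds[key]
        if not pooled_values:
            return None
        return derive_median(pooled_values)

    th = {
        "temporal": threshold(
            "temporal",
            [r.pearson_r for recs in time_co.values() for r in recs if r.pearson_r is not None],
        ),
        "spatial_expr": threshold(
            "spatial_expr",
            [r.pearson_r for recs in expr_co.values() for r in recs if r.pearson_r is not None],
        ),
        "spatial_promoter": threshold(
            "spatial_promoter",
            [r.pearson_r for recs in prom_co.values() for r in recs if r.pearson_r is not None],
        ),
        "balance_time": threshold(
            "balance_time",
            [
                r.mean_abs_log10_diff
                for recs in time_im.values()
                for r in recs
                if r.mean_abs_log10_diff is not None
            ],
        ),
        "balance_space_expr": threshold(
            "balance_space_expr",
            [
                r.mean_abs_log10_diff
                for recs in expr_im.values()
                for r in recs
                if r.mean_abs_log10_diff is not None
            ],
        ),
        "balance_space_promoter": threshold(
            "balance_space_promoter",
            [
                r.mean_abs_log10_diff
                for recs in prom_im.values()
                for r in recs
                if r.mean_abs_log10_diff is not None
            ],
        ),
    }

    def first_defined_co(recs: list[CoexpressionRecord]) -> CoexpressionRecord | None:
        for r in recs:
            if r.pearson_r is not None:
                return r
        return None

    labels: dict[str, ClassificationLabels] = {}
    for ppi in interactome.ppis:
        lab = ClassificationLabels(ppi_id=ppi.id)
        lab.strength = classify_strength(ppi.delta_g, config.dg_weak_cutoff)
        if th["temporal"] is not None:
            lab.temporal = classify_temporal(time_co[ppi.id], th["temporal"])
        for key, co in (("spatial_expr", expr_co), ("spatial_promoter", prom_co)):
            rec = first_defined_co(co[ppi.id])
            if th[key] is not None and rec is not None:
                lab.__setattr__(key, classify_spatial(rec, th[key]))
        if th["balance_time"] is not None:
            lab.balance_time = classify_balance(
                time_im[ppi.id], th["balance_time"], majority_mode=True
            )
        for key, im in (
            ("balance_space_expr", expr_im),
            ("balance_space_promoter", prom_im),
        ):
            defined = [r for r in im[ppi.id] if r.mean_abs_log10_diff is not None]
            if th[key] is not None and defined:
                lab.__setattr__(
                    key,
                    classify_balance(defined[:1], th[key], majority_mode=False),
                )
        _, lab.exclusivity_bin = count_mutually_exclusive(
            interactome, ppi, config.overlap_threshold
        )
        labels[ppi.id] = lab
    return labels


# ---------------------------------------------------------------------------
# I/O: expression matrices (genes x conditions TSV + manifest), labels TSV
# ---------------------------------------------------------------------------

def write_expression_tsv(experiment: ExpressionExperiment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(experiment.condition_labels) + "\n")
        for gene, values in experiment.matrix.items():
            cells = ["" if math.isnan(v) else repr(float(v)) for v in values]
            fh.write(gene + "\t" + "\t".join(cells) + "\n")


def read_expression_tsv(
    path: str | Path, experiment_id: str, kind: str
) -> ExpressionExperiment:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        condition_labels = header[1:]
        matrix: dict[str, list[float]] = {}
        for line in fh:
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            matrix[cells[0]] = [
                float(c) if c else float("nan") for c in cells[1:]
            ]
    return ExpressionExperiment(
        experiment_id=experiment_id,
        kind=kind,
        matrix=matrix,
        condition_labels=condition_labels,
    )


def write_manifest_tsv(
    entries: Sequence[tuple[str, str, str]], path: str | Path
) -> None:
    """Entries are (experiment_id, kind, filename) rows."""
    with open(path, "w") as fh:
        fh.write("experiment_id\tkind\tfile\n")
        for exp_id, kind, fname in entries:
            fh.write(f"{exp_id}\t{kind}\t{fname}\n")


def read_manifest_tsv(path: str | Path) -> list[tuple[str, str, str]]:
    entries = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if line.strip():
                exp_id, kind, fname = line.rstrip("\n").split("\t")
                entries.append((exp_id, kind, fname))
    return entries


_LABEL_FIELDS = (
    "strength",
    "temporal",
    "spatial_expr",
    "spatial_promoter",
    "balance_time",
    "balance_space_expr",
    "balance_space_promoter",
    "exclusivity_bin",
)


def write_labels_tsv(
    labels: Mapping[str, ClassificationLabels], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("ppi_id\t" + "\t".join(_LABEL_FIELDS) + "\n")
        for ppi_id, lab in labels.items():
            fh.write(
                ppi_id
                + "\t"
                + "\t".join(getattr(lab, f) for f in _LABEL_FIELDS)
                + "\n"
            )


def read_labels_tsv(path: str | Path) -> dict[str, ClassificationLabels]:
    labels = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "ppi_id":
            raise InvalidInputError(f"{path}: unexpected labels header")
        for line in fh:
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            kwargs = dict(zip(header[1:], cells[1:]))
            labels[cells[0]] = ClassificationLabels(ppi_id=cells[0], **kwargs)
    return labels
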