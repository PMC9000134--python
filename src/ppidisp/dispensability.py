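"""Bayesian estimation of dispensable PPI content.

Given the per-class proportions of mutations that edgetically disrupt a
PPI group T — P(T|N) for effectively neutral (common) mutations and
P(T|M) for mildly deleterious (disease) mutations — and prior
probabilities for a new missense mutation to be neutral, mildly
deleterious, or strongly detrimental, the marginal disruption
probability is

    P(T) = P(T|N) P(N) + P(T|M) P(M) + P(T|S) P(S)

with P(T|S) = 0 (strongly detrimental mutations are assumed quasi-null
rather than edgetic). Bayes' theorem then gives the dispensable content

    P(N|T) = P(T|N) P(N) / P(T)

which depends only on the two ratios through the equivalent closed form

    1 / P(N|T) = 1 + (P(M)/P(N)) * (P(T|M)/P(T|N)).

95% confidence intervals come from the normal-approximation interval for
the log ratio of two proportions, with standard error
sqrt(1/a - 1/n1 + 1/b - 1/n2), mapped through the monotone closed form.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

from scipy.stats import norm

from ppidisp.classify import PROPERTY_GROUPS, ClassificationLabels
from ppidisp.edgotype import EdgotypeCounts, predict_disruptions, tabulate
from ppidisp.interactome import Interactome, InvalidInputError
from ppidisp.mutations import MutationRecord, locate_interfacial

_PRIOR_TOL = 1e-9


@dataclass(frozen=True)
class PriorSet:
    """Prior probabilities for a new missense mutation's fitness class."""

    p_neutral: float = 0.27
    p_mild: float = 0.53
    p_detrimental: float = 0.20

    def __post_init__(self) -> None:
        for name, p in (
            ("p_neutral", self.p_neutral),
            ("p_mild", self.p_mild),
            ("p_detrimental", self.p_detrimental),
        ):
            if not (0.0 <= p <= 1.0):
                raise InvalidInputError(f"{name} must lie in [0, 1]")
        total = self.p_neutral + self.p_mild + self.p_detrimental
        if abs(total - 1.0) > _PRIOR_TOL:
            raise InvalidInputError(f"priors must sum to 1 (got {total!r})")


@dataclass(frozen=True)
class EdgotypeRates:
    """Per-class disruption proportions with their underlying counts."""

    p_T_given_N: float
    p_T_given_M: float
    p_T_given_S: float = 0.0
    n_count: tuple[int, int] = (0, 0)  # (numerator, denominator) neutral class
    m_count: tuple[int, int] = (0, 0)  # (numerator, denominator) mild class

    def __post_init__(self) -> None:
        for name, p in (
            ("p_T_given_N", self.p_T_given_N),
            ("p_T_given_M", self.p_T_given_M),
            ("p_T_given_S", self.p_T_given_S),
        ):
            if not (0.0 <= p <= 1.0):
                raise InvalidInputError(f"{name} must lie in [0, 1]")
        for (num, den), p in ((self.n_count, self.p_T_given_N), (self.m_count, self.p_T_given_M)):
            if den > 0 and abs(num / den - p) > 1e-12:
                raise InvalidInputError("rate inconsistent with its counts")


@dataclass
class DispensableEstimate:
    """Point estimate of dispensable content with optional 95% CI."""

    p_T: float
    p_N_given_T: float
    ratio: float | None  # P(T|N) / P(T|M)
    ci_low: float | None = None
    ci_high: float | None = None
    defined: bool = True
    ci_corrected: bool = False


class ConfidenceInterval(NamedTuple):
    low: float
    high: float
    corrected: bool = False


def rates_from_counts(counts: EdgotypeCounts, group: str = "T") -> EdgotypeRates:
    """Disruption proportions for one PPI group from a count row."""
    if group not in ("T", "P"):
        raise InvalidInputError("group must be 'T' or 'P'")
    a = getattr(counts, f"common_disrupt_{group}")
    n1 = counts.common_total
    b = getattr(counts, f"disease_disrupt_{group}")
    n2 = counts.disease_total
    if n1 <= 0 or n2 <= 0:
        raise InvalidInputError("rates require positive denominators")
    return EdgotypeRates(
        p_T_given_N=a / n1,
        p_T_given_M=b / n2,
        n_count=(a, n1),
        m_count=(b, n2),
    )


def dispensable_content(rates: EdgotypeRates, priors: PriorSet | None = None) -> DispensableEstimate:
    """Dispensable content P(N|T) via the marginal and Bayes' theorem."""
    priors = priors or PriorSet()
    p_T = (
        rates.p_T_given_N * priors.p_neutral
        + rates.p_T_given_M * priors.p_mild
        + rates.p_T_given_S * priors.p_detrimental
    )
    ratio = (
        rates.p_T_given_N / rates.p_T_given_M if rates.p_T_given_M > 0 else None
    )
    if p_T == 0:
        return DispensableEstimate(p_T=0.0, p_N_given_T=float("nan"), ratio=ratio, defined=False)
    return DispensableEstimate(
        p_T=p_T,
        p_N_given_T=rates.p_T_given_N * priors.p_neutral / p_T,
        ratio=ratio,
    )


def content_from_ratio(rate_ratio: float, priors: PriorSet) -> float:
    """Closed form: P(N|T) = 1 / (1 + (P(M)/P(N)) / (P(T|N)/P(T|M)))."""
    if rate_ratio < 0:
        raise InvalidInputError("rate ratio must be non-negative")
    if rate_ratio == 0:
        return 0.0
    return 1.0 / (1.0 + (priors.p_mild / priors.p_neutral) / rate_ratio)


def bland_ci(
    counts: tuple[int, int, int, int],
    priors: PriorSet | None = None,
    level: float = 0.95,
) -> ConfidenceInterval:
    """CI on dispensable content from the log ratio-of-proportions interval.

    ``counts`` is (a, n1, b, n2): a/n1 is the neutral-class proportion,
    b/n2 the mild-class proportion. The interval for r = (a/n1)/(b/n2)
    uses SE(ln r) = sqrt(1/a - 1/n1 + 1/b - 1/n2); each ratio endpoint
    is mapped through the monotone closed form onto P(N|T). Zero
    numerators trigger a Haldane-Anscombe correction (+0.5 to all four
    counts), flagged via ``corrected``.
    """
    priors = priors or PriorSet()
    a, n1, b, n2 = counts
    if min(n1, n2) <= 0 or a < 0 or b < 0 or a > n1 or b > n2:
        raise InvalidInputError("invalid count tuple")
    corrected = a == 0 or b == 0
    if corrected:
        a, n1, b, n2 = a + 0.5, n1 + 0.5, b + 0.5, n2 + 0.5
    r = (a / n1) / (b / n2)
    se = math.sqrt(1 / a - 1 / n1 + 1 / b - 1 / n2)
    z = norm.ppf(0.5 + level / 2)
    r_low = r * math.exp(-z * se)
    r_high = r * math.exp(z * se)
    return ConfidenceInterval(
        low=content_from_ratio(r_low, priors),
        high=content_from_ratio(r_high, priors),
        corrected=corrected,
    )


def estimate_from_counts(
    counts: EdgotypeCounts,
    group: str = "T",
    priors: PriorSet | None = None,
    level: float = 0.95,
) -> DispensableEstimate:
    """Point estimate plus CI for one group of one count row."""
    priors = priors or PriorSet()
    rates = rates_from_counts(counts, group)
    est = dispensable_content(rates, priors)
    if rates.p_T_given_M > 0 or rates.p_T_given_N > 0:
        ci = bland_ci((*rates.n_count, *rates.m_count), priors, level)
        est.ci_low, est.ci_high, est.ci_corrected = ci.low, ci.high, ci.corrected
    return est


def prior_sensitivity(
    rates: EdgotypeRates,
    prior_grid: Iterable[PriorSet],
) -> list[tuple[PriorSet, DispensableEstimate]]:
    """Dispensable content at each prior in the grid.

    The uninformative point P(M)/P(N) = 1 should be part of the grid to
    reproduce the upper-bound analysis; :func:`uninformative_priors`
    provides it.
    """
    return [(p, dispensable_content(rates, p)) for p in prior_grid]


def uninformative_priors(p_detrimental: float = 0.20) -> PriorSet:
    """Priors with P(M)/P(N) = 1, keeping the detrimental mass fixed."""
    rest = (1.0 - p_detrimental) / 2.0
    return PriorSet(p_neutral=rest, p_mild=rest, p_detrimental=p_detrimental)


# ---------------------------------------------------------------------------
# Report rows at the published table's printed precision
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReportRow:
    """One report row: both groups of one property, printed-precision fields.

    Percentages are rounded to 1 decimal. The printed ratio column is
    the quotient of the two *rounded* percentages, rounded to 2 decimals
    (the convention of the source table; the exact ratio is available
    from :class:`DispensableEstimate`). Permanent-group fields are None
    when the row has no permanent counts.
    """

    dataset: str
    property_name: str
    pct_T_given_N: float
    pct_T_given_M: float
    ratio_T: float
    pct_N_given_T: float
    ci_T: tuple[float, float]
    pct_P_given_N: float | None = None
    pct_P_given_M: float | None = None
    ratio_P: float | None = None
    pct_N_given_P: float | None = None
    ci_P: tuple[float, float] | None = None


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (the spreadsheet convention, not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def printed_ratio(pct_n: float, pct_m: float) -> float:
    """Ratio of the two 1-decimal-rounded percentages, rounded to 2 decimals."""
    rn, rm = round(pct_n, 1), round(pct_m, 1)
    if rm == 0:
        return float("inf")
    return round(rn / rm, 2)


def printed_content_percent(p: float) -> float:
    """Dispensable content as a printed percentage.

    The source table's content columns are rounded half-up with an
    intermediate 2-decimal stage (0.118499 prints as 11.9, not 11.8);
    the proportion columns use plain 1-decimal rounding instead.
    """
    return round_half_up(round_half_up(100 * p, 2), 1)


def report_row(
    counts: EdgotypeCounts,
    dataset: str = "",
    priors: PriorSet | None = None,
    level: float = 0.95,
    has_permanent: bool = True,
) -> ReportRow:
    priors = priors or PriorSet()

    def one_group(group: str):
        rates = rates_from_counts(counts, group)
        est = estimate_from_counts(counts, group, priors, level)
        pct_n = round(100 * rates.p_T_given_N, 1)
        pct_m = round(100 * rates.p_T_given_M, 1)
        return (
            pct_n,
            pct_m,
            printed_ratio(100 * rates.p_T_given_N, 100 * rates.p_T_given_M),
            printed_content_percent(est.p_N_given_T),
            (
                (round(100 * est.ci_low, 1), round(100 * est.ci_high, 1))
                if est.ci_low is not None
                else (float("nan"), float("nan"))
            ),
        )

    t = one_group("T")
    p = one_group("P") if has_permanent else (None, None, None, None, None)
    return ReportRow(
        dataset=dataset,
        property_name=counts.property_name,
        pct_T_given_N=t[0],
        pct_T_given_M=t[1],
        ratio_T=t[2],
        pct_N_given_T=t[3],
        ci_T=t[4],
        pct_P_given_N=p[0],
        pct_P_given_M=p[1],
        ratio_P=p[2],
        pct_N_given_P=p[3],
        ci_P=p[4],
    )


def run_full_analysis(
    interactome: Interactome,
    mutations: Sequence[MutationRecord],
    labels: Mapping[str, ClassificationLabels],
    priors: PriorSet | None = None,
    ddg_cutoff: float = 0.5,
    properties: Sequence[str] | None = None,
    level: float = 0.95,
    mono_edgetic: bool = False,
) -> tuple[list[EdgotypeCounts], list[ReportRow]]:
    """End-to-end: disruption prediction, tabulation, and estimation.

    Returns the count rows (published-table-1 shape) and the report rows
    (published-table-2 shape) for every requested property family.
    """
    priors = priors or PriorSet()
    properties = list(properties or PROPERTY_GROUPS)
    if len({m.id for m in mutations}) != len(mutations):
        raise InvalidInputError("mutation ids must be unique across the cohort")
    interfacial_map = locate_interfacial(mutations, interactome)
    ppis_by_protein: dict[str, list[str]] = {}
    for ppi in interactome.ppis:
        for pid in set(ppi.partners()):
            ppis_by_protein.setdefault(pid, []).append(ppi.id)
    calls = {
        mut.id: predict_disruptions(mut, interfacial_map.get(mut.id, ()), ddg_cutoff)
        for mut in mutations
    }
    count_rows: list[EdgotypeCounts] = []
    report_rows: list[ReportRow] = []
    for prop in properties:
        counts = tabulate(
            mutations, calls, labels, prop, ppis_by_protein, mono_edgetic
        )
        count_rows.append(counts)
        if counts.common_total == 0 or counts.disease_total == 0:
            continue
        report_rows.append(
            report_row(counts, interactome.name, priors, level)
        )
    return count_rows, report_rows


# ---------------------------------------------------------------------------
# Published count table (printed inputs) and report I/O
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PublishedCounts:
    """One row of the published per-property disruption count table."""

    dataset: str
    property_name: str
    common_total: int
    common_disrupt_T: int
    common_disrupt_P: int | None
    disease_total: int
    disease_disrupt_T: int
    disease_disrupt_P: int | None

    def as_counts(self) -> EdgotypeCounts:
        return EdgotypeCounts(
            property_name=self.property_name,
            group_pair=("T", "P"),
            common_total=self.common_total,
            common_disrupt_T=self.common_disrupt_T,
            common_disrupt_P=self.common_disrupt_P or 0,
            disease_total=self.disease_total,
            disease_disrupt_T=self.disease_disrupt_T,
            disease_disrupt_P=self.disease_disrupt_P or 0,
        )

    @property
    def has_permanent(self) -> bool:
        return self.common_disrupt_P is not None and self.disease_disrupt_P is not None


def published_counts() -> list[PublishedCounts]:
    """The published disruption count table shipped as package data."""
    rows = []
    text = (
        resources.files("ppidisp").joinpath("data/published_counts.tsv").read_text()
    )
    lines = text.strip("\n").split("\n")
    header = lines[0].split("\t")
    for line in lines[1:]:
        cells = line.split("\t")
        cells += [""] * (len(header) - len(cells))
        rec = dict(zip(header, cells))
        rows.append(
            PublishedCounts(
                dataset=rec["dataset"],
                property_name=rec["property_name"],
                common_total=int(rec["common_total"]),
                common_disrupt_T=int(rec["common_disrupt_T"]),
                common_disrupt_P=(
                    int(rec["common_disrupt_P"]) if rec["common_disrupt_P"] else None
                ),
                disease_total=int(rec["disease_total"]),
                disease_disrupt_T=int(rec["disease_disrupt_T"]),
                disease_disrupt_P=(
                    int(rec["disease_disrupt_P"]) if rec["disease_disrupt_P"] else None
                ),
            )
        )
    return rows


def published_counts_row(dataset: str, property_name: str) -> PublishedCounts:
    for row in published_counts():
        if row.dataset == dataset and row.property_name == property_name:
            return row
    raise KeyError(f"no published row for ({dataset!r}, {property_name!r})")


_REPORT_FIELDS = (
    "dataset",
    "property_name",
    "pct_T_given_N",
    "pct_T_given_M",
    "ratio_T",
    "pct_N_given_T",
    "ci_T_low",
    "ci_T_high",
    "pct_P_given_N",
    "pct_P_given_M",
    "ratio_P",
    "pct_N_given_P",
    "ci_P_low",
    "ci_P_high",
)


def _row_record(row: ReportRow) -> dict:
    rec = {
        "dataset": row.dataset,
        "property_name": row.property_name,
        "pct_T_given_N": row.pct_T_given_N,
        "pct_T_given_M": row.pct_T_given_M,
        "ratio_T": row.ratio_T,
        "pct_N_given_T": row.pct_N_given_T,
        "ci_T_low": row.ci_T[0],
        "ci_T_high": row.ci_T[1],
        "pct_P_given_N": row.pct_P_given_N,
        "pct_P_given_M": row.pct_P_given_M,
        "ratio_P": row.ratio_P,
        "pct_N_given_P": row.pct_N_given_P,
        "ci_P_low": row.ci_P[0] if row.ci_P else None,
        "ci_P_high": row.ci_P[1] if row.ci_P else None,
    }
    return rec


def write_report_tsv(rows: Iterable[ReportRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_REPORT_FIELDS) + "\n")
        for row in rows:
            rec = _row_record(row)
            fh.write(
                "\t".join("" if rec[f] is None else str(rec[f]) for f in _REPORT_FIELDS)
                + "\n"
            )


def write_report_json(rows: Iterable[ReportRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([_row_record(r) for r in rows], fh, indent=2)
        fh.write("\n")
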