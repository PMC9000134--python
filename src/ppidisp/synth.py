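"""Seeded synthetic input bundles with known ground truth.

The generator produces a toy structural interactome (with coordinates
whose geometric interfaces equal the declared interface sets exactly),
expression experiments built from a bivariate-normal construction on the
log scale, and mutation cohorts whose per-class disruption rates are
known by construction, so the full pipeline and the Bayesian estimator
can be exercised and validated offline.

Toy coordinates are synthetic point clouds, not physical proteins:
paired interface atoms sit 3 angstrom apart across chains (inside the
5 angstrom contact rule with margin) and non-interface residues are
placed far from the other chain (>= 8 angstrom). ddG values are drawn
from normals truncated at 0 (destabilizing-only), conditioned on the
intended side of the disruption cutoff so realized disruption indicators
are exact Bernoulli draws at the configured rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import truncnorm

from ppidisp.classify import (
    ExpressionExperiment,
    read_expression_tsv,
    read_manifest_tsv,
    write_expression_tsv,
    write_manifest_tsv,
)
from ppidisp.dispensability import PriorSet, content_from_ratio
from ppidisp.interactome import (
    ChainStructure,
    Interactome,
    InvalidInputError,
    PPIRecord,
    Protein,
    read_fasta,
    read_interactome_tsv,
    write_fasta,
    write_interactome_tsv,
)
from ppidisp.mutations import (
    MutationRecord,
    attach_effects_tsv,
    read_mutations_tsv,
    write_effects_tsv,
    write_mutations_tsv,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic bundle generator; ``seed`` fixes everything."""

    n_proteins: int = 60
    n_ppis: int = 80
    hub_fraction: float = 0.1
    hub_degree: int = 6
    weak_fraction: float = 0.57
    dg_weak_mean: float = -15.0
    dg_weak_sd: float = 5.0
    dg_strong_mean: float = -35.0
    dg_strong_sd: float = 5.0
    coexpr_targets: tuple[float, float] = (-0.5, 1.0)  # uniform range
    imbalance_offset_sd: float = 0.5
    n_time_experiments: int = 3
    n_time_points: int = 8
    n_tissues: int = 16
    n_common: int = 200
    n_disease: int = 200
    interfacial_fraction: float = 0.3
    ddg_mean_common: float = 0.33
    ddg_mean_disease: float = 1.1
    ddg_sd: float = 0.4
    ddg_cutoff: float = 0.5
    true_disrupt_rate_common: float = 0.01
    true_disrupt_rate_disease: float = 0.05
    interface_size: int = 4
    log_expr_mean: float = 1.0
    log_expr_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "hub_fraction",
            "weak_fraction",
            "interfacial_fraction",
            "true_disrupt_rate_common",
            "true_disrupt_rate_disease",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidInputError(f"{name} must lie in [0, 1]")
        for name in ("n_proteins", "n_ppis", "n_common", "n_disease", "n_tissues"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if self.n_time_points < 5:
            raise InvalidInputError("time-course experiments need >=5 points")
        if self.interfacial_fraction > 0:
            for name in ("true_disrupt_rate_common", "true_disrupt_rate_disease"):
                if getattr(self, name) > self.interfacial_fraction:
                    raise InvalidInputError(
                        f"{name} cannot exceed interfacial_fraction"
                    )

    def streams(self) -> tuple[np.random.Generator, ...]:
        """Independent per-stage RNG streams derived from the master seed."""
        seqs = np.random.SeedSequence(self.seed).spawn(3)
        return tuple(np.random.default_rng(s) for s in seqs)


@dataclass
class GroundTruth:
    """What the generator intended, for parameter-recovery checks."""

    disruption_target: dict[str, str | None]  # mutation id -> disrupted PPI id
    rate_common: float
    rate_disease: float
    priors: PriorSet

    @property
    def analytic_dispensable(self) -> float:
        """Closed-form dispensable content implied by the configured rates."""
        if self.rate_disease == 0:
            return 1.0
        return content_from_ratio(self.rate_common / self.rate_disease, self.priors)


@dataclass
class Bundle:
    interactome: Interactome
    chain_models: dict[str, tuple[ChainStructure, ChainStructure]]
    experiments: list[ExpressionExperiment]
    promoter_experiment_ids: tuple[str, ...]
    common: list[MutationRecord]
    disease: list[MutationRecord]
    truth: GroundTruth


def _truncnorm_sample(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    low: float = -np.inf,
    high: float = np.inf,
    size: int | None = None,
):
    a, b = (low - mean) / sd, (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _toy_chains(
    iface_a: Sequence[int], iface_b: Sequence[int], seq_len_a: int, seq_len_b: int
) -> tuple[ChainStructure, ChainStructure]:
    """Two point-cloud chains whose 5-angstrom interface equals the declared sets.

    Every interface residue receives at least one atom 3 angstrom from
    the partner chain; non-interface residues sit >= 8 angstrom away.
    Chain residue numbering equals protein sequence numbering (identity
    mapping).
    """
    ia, ib = sorted(iface_a), sorted(iface_b)
    atoms_a: dict[int, list[list[float]]] = {}
    atoms_b: dict[int, list[list[float]]] = {}
    n_pairs = max(len(ia), len(ib))
    for k in range(n_pairs):
        x = 8.0 * k
        atoms_a.setdefault(ia[k % len(ia)], []).append([x, 0.0, 0.0])
        atoms_b.setdefault(ib[k % len(ib)], []).append([x, 3.0, 0.0])
    far = 8.0 * (n_pairs + 2)
    for pos in range(1, seq_len_a + 1):
        if pos not in atoms_a:
            atoms_a[pos] = [[far + 8.0 * pos, 100.0, 0.0]]
    for pos in range(1, seq_len_b + 1):
        if pos not in atoms_b:
            atoms_b[pos] = [[far + 8.0 * pos, -100.0, 0.0]]
    chain_a = ChainStructure(
        "A", [(p, np.array(atoms_a[p])) for p in sorted(atoms_a)]
    )
    chain_b = ChainStructure(
        "B", [(p, np.array(atoms_b[p])) for p in sorted(atoms_b)]
    )
    return chain_a, chain_b


def generate_interactome(config: GeneratorConfig) -> tuple[
    Interactome, dict[str, tuple[ChainStructure, ChainStructure]]
]:
    """A toy interactome with date hubs, disjoint party interfaces, and dG values.

    Hub proteins reuse a single interface block across all their PPIs
    (mutually exclusive binding); every other interface is a fresh
    disjoint block, so with ``hub_fraction`` 0 all exclusivity bins are
    '0'. Binding free energies are drawn from a two-component mixture
    split at -25 kcal/mol with the configured weak share.
    """
    rng, _, _ = config.streams()
    n = config.n_proteins
    max_pairs = n * (n - 1) // 2
    if config.n_ppis > max_pairs:
        raise InvalidInputError(
            f"n_ppis={config.n_ppis} exceeds the {max_pairs} possible pairs"
        )
    block = config.interface_size
    n_hubs = int(round(config.hub_fraction * n))
    pair_set: set[frozenset[str]] = set()
    pairs: list[tuple[int, int]] = []  # protein index pairs
    hub_of_pair: list[int | None] = []  # hub index or None

    def add_pair(i: int, j: int, hub: int | None) -> bool:
        key = frozenset((f"P{i}", f"P{j}"))
        if i == j or key in pair_set:
            return False
        pair_set.add(key)
        pairs.append((i, j))
        hub_of_pair.append(hub)
        return True

    # Date-hub PPIs: hub h binds `degree` partners through one interface.
    for h in range(n_hubs):
        degree = config.hub_degree if h % 2 == 0 else 3
        partners = rng.choice(
            np.arange(n_hubs, n), size=min(degree, n - n_hubs), replace=False
        )
        for j in partners:
            if len(pairs) < config.n_ppis:
                add_pair(h, int(j), hub=h)
    # Fill with random non-hub party PPIs on disjoint interfaces.
    attempts = 0
    while len(pairs) < config.n_ppis and attempts < 50 * config.n_ppis:
        i, j = rng.integers(n_hubs, n, size=2) if n - n_hubs >= 2 else rng.integers(0, n, size=2)
        add_pair(int(i), int(j), hub=None)
        attempts += 1
    if len(pairs) < config.n_ppis:
        raise InvalidInputError("could not place the requested number of PPIs")

    # Allocate interface blocks: hubs get one shared block, everything
    # else a fresh disjoint block per PPI role.
    cursor = np.full(n, 1, dtype=int)  # next free 1-based position
    hub_block: dict[int, tuple[int, ...]] = {}

    def fresh_block(prot: int) -> tuple[int, ...]:
        start = int(cursor[prot])
        cursor[prot] = start + block
        return tuple(range(start, start + block))

    iface_pairs: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
    for (i, j), hub in zip(pairs, hub_of_pair):
        if hub is not None:
            if hub not in hub_block:
                hub_block[hub] = fresh_block(hub)
            block_i = hub_block[hub] if i == hub else fresh_block(i)
            block_j = hub_block[hub] if j == hub else fresh_block(j)
        else:
            block_i, block_j = fresh_block(i), fresh_block(j)
        iface_pairs.append((block_i, block_j))

    seq_lens = np.maximum(cursor - 1 + 12, 30)
    proteins = [
        Protein(
            id=f"P{i}",
            sequence="".join(rng.choice(list(_AA), size=int(seq_lens[i]))),
        )
        for i in range(n)
    ]

    weak = rng.random(len(pairs)) < config.weak_fraction
    dgs = np.where(
        weak,
        _truncnorm_sample(
            rng, config.dg_weak_mean, config.dg_weak_sd, low=-25.0, size=len(pairs)
        ),
        _truncnorm_sample(
            rng, config.dg_strong_mean, config.dg_strong_sd, high=-25.0 - 1e-9, size=len(pairs)
        ),
    )

    ppis = []
    chain_models: dict[str, tuple[ChainStructure, ChainStructure]] = {}
    for idx, ((i, j), (bi, bj)) in enumerate(zip(pairs, iface_pairs)):
        ppi = PPIRecord(
            partner_a=f"P{i}",
            partner_b=f"P{j}",
            interface_a=frozenset(bi),
            interface_b=frozenset(bj),
            delta_g=float(dgs[idx]),
            template=(f"synt{idx}", ("A", "B")),
        )
        ppis.append(ppi)
        chain_models[ppi.id] = _toy_chains(
            bi, bj, int(seq_lens[i]), int(seq_lens[j])
        )
    interactome = Interactome(proteins=proteins, ppis=ppis, name=f"synthetic-{config.seed}")
    return interactome, chain_models


def correlated_pair(
    rng: np.random.Generator,
    n_conditions: int,
    rho: float,
    offset: float,
    log_mean: float = 1.0,
    log_sd: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Two positive profiles from a bivariate normal on the log10 scale.

    The log-scale correlation equals ``rho`` in expectation and the mean
    log10 difference equals ``offset``.
    """
    if not (-1.0 <= rho <= 1.0):
        raise InvalidInputError("rho must lie in [-1, 1]")
    za = rng.standard_normal(n_conditions)
    eps = rng.standard_normal(n_conditions)
    zb = rho * za + math.sqrt(max(0.0, 1.0 - rho * rho)) * eps
    log_a = log_mean + log_sd * za
    log_b = log_mean - offset + log_sd * zb
    return 10.0 ** log_a, 10.0 ** log_b


def generate_expression(
    config: GeneratorConfig, interactome: Interactome
) -> tuple[list[ExpressionExperiment], tuple[str, ...], dict[str, tuple[float, float]]]:
    """Time-course and tissue experiments with per-pair targets.

    Each PPI gets a co-expression target (uniform on the configured
    range) and a log10 abundance offset; partner profiles are built
    PPI-by-PPI, first assignment winning when a protein participates in
    several PPIs. Returns the experiments, the promoter-source
    experiment ids, and the per-PPI (target_r, offset) map.
    """
    _, rng, _ = config.streams()
    lo, hi = config.coexpr_targets
    targets = {
        ppi.id: (
            float(rng.uniform(lo, hi)),
            float(abs(rng.normal(0.0, config.imbalance_offset_sd))),
        )
        for ppi in interactome.ppis
    }

    specs = [
        (f"time_{k}", "time_course", config.n_time_points)
        for k in range(config.n_time_experiments)
    ]
    specs.append(("tissue_expr", "tissue", config.n_tissues))
    specs.append(("tissue_promoter", "tissue", config.n_tissues))

    experiments = []
    for exp_id, kind, n_cond in specs:
        matrix: dict[str, list[float]] = {}
        for ppi in interactome.ppis:
            a, b = ppi.partners()
            rho, offset = targets[ppi.id]
            if a in matrix and b in matrix:
                continue
            if a in matrix:
                za = (np.log10(np.asarray(matrix[a])) - config.log_expr_mean) / config.log_expr_sd
                eps = rng.standard_normal(n_cond)
                zb = rho * za + math.sqrt(max(0.0, 1 - rho * rho)) * eps
                matrix[b] = list(10.0 ** (config.log_expr_mean - offset + config.log_expr_sd * zb))
            else:
                xa, xb = correlated_pair(
                    rng, n_cond, rho, offset, config.log_expr_mean, config.log_expr_sd
                )
                if a not in matrix:
                    matrix[a] = list(xa)
                if b not in matrix:
                    matrix[b] = list(xb)
        labels = [f"{kind[:4]}{i}" for i in range(n_cond)]
        experiments.append(
            ExpressionExperiment(
                experiment_id=exp_id, kind=kind, matrix=matrix, condition_labels=labels
            )
        )
    return experiments, ("tissue_promoter",), targets


def generate_mutations(
    config: GeneratorConfig,
    interactome: Interactome,
    priors: PriorSet | None = None,
    seed: int | None = None,
) -> tuple[list[MutationRecord], list[MutationRecord], GroundTruth]:
    """Common and disease cohorts with exact Bernoulli disruption ground truth.

    Each mutation targets one PPI (uniform over PPIs) on one partner; it
    is interfacial with probability ``interfacial_fraction`` and, if so,
    disrupts its target with probability rate/interfacial_fraction, so
    the unconditional disruption probability equals the configured class
    rate. ddG values are drawn conditioned on the intended side of the
    cutoff, from truncated normals at the class mean. ``seed``
    optionally overrides the config-derived mutation stream (used for
    replicate studies on a fixed interactome).
    """
    priors = priors or PriorSet()
    if seed is None:
        _, _, rng = config.streams()
    else:
        rng = np.random.default_rng(seed)

    ppis = interactome.ppis
    disruption_target: dict[str, str | None] = {}

    # Per-protein caches shared by both cohorts (hot loop below).
    ppis_of: dict[str, list[PPIRecord]] = {}
    for q in ppis:
        for pid in set(q.partners()):
            ppis_of.setdefault(pid, []).append(q)
    iface_sorted = {
        (q.id, pid): sorted(q.interface_of(pid))
        for q in ppis
        for pid in set(q.partners())
    }
    free_positions: dict[str, list[int]] = {}
    for pid, prot in interactome.proteins.items():
        all_iface = set().union(
            *(q.interface_of(pid) for q in ppis_of.get(pid, [])), set()
        )
        free_positions[pid] = [
            p for p in range(1, len(prot.sequence) + 1) if p not in all_iface
        ]
    alt_residues = {wt: [aa for aa in _AA if aa != wt] for wt in _AA}

    def make_cohort(n: int, mclass: str, rate: float, ddg_mean: float):
        cohort: list[MutationRecord] = []
        ppi_idx = rng.integers(0, len(ppis), size=n)
        side = rng.random(n) < 0.5
        interfacial = rng.random(n) < config.interfacial_fraction
        p_disrupt = (
            rate / config.interfacial_fraction if config.interfacial_fraction > 0 else 0.0
        )
        disrupt = interfacial & (rng.random(n) < p_disrupt)
        n_hit = int(disrupt.sum())
        n_miss = int(interfacial.sum()) - n_hit
        ddg_hit = _truncnorm_sample(
            rng, ddg_mean, config.ddg_sd, low=config.ddg_cutoff + 1e-12, size=n_hit
        )
        ddg_miss = _truncnorm_sample(
            rng, ddg_mean, config.ddg_sd, low=0.0, high=config.ddg_cutoff, size=n_miss
        )
        i_hit = i_miss = 0
        mafs = rng.uniform(0.01, 0.5, size=n)
        pos_draws = rng.random(n)  # one uniform per mutation for position choice
        mut_draws = rng.random(n)
        for k in range(n):
            ppi = ppis[int(ppi_idx[k])]
            pid = ppi.partner_a if side[k] else ppi.partner_b
            protein = interactome.proteins[pid]
            if interfacial[k]:
                choices = iface_sorted[(ppi.id, pid)]
            else:
                choices = free_positions[pid]
            pos = choices[int(pos_draws[k] * len(choices))]
            wt = protein.sequence[pos - 1]
            alts = alt_residues[wt]
            mut = alts[int(mut_draws[k] * len(alts))]
            rec = MutationRecord(
                protein_id=pid,
                position=pos,
                wt_residue=wt,
                mut_residue=mut,
                mclass=mclass,
                maf=float(mafs[k]) if mclass == "common" else None,
                record_id=f"{mclass}_{k}",
            )
            if interfacial[k]:
                if disrupt[k]:
                    rec.effects[ppi.id] = float(ddg_hit[i_hit])
                    i_hit += 1
                else:
                    rec.effects[ppi.id] = float(ddg_miss[i_miss])
                    i_miss += 1
                # sub-cutoff ddG for any other PPI sharing this position
                for other in ppis_of.get(pid, ()):
                    if other.id != ppi.id and pos in other.interface_of(pid):
                        rec.effects[other.id] = float(
                            _truncnorm_sample(
                                rng, ddg_mean, config.ddg_sd, low=0.0,
                                high=config.ddg_cutoff,
                            )
                        )
            disruption_target[rec.id] = ppi.id if disrupt[k] else None
            cohort.append(rec)
        return cohort

    common = make_cohort(
        config.n_common, "common", config.true_disrupt_rate_common, config.ddg_mean_common
    )
    disease = make_cohort(
        config.n_disease, "disease", config.true_disrupt_rate_disease, config.ddg_mean_disease
    )
    truth = GroundTruth(
        disruption_target=disruption_target,
        rate_common=config.true_disrupt_rate_common,
        rate_disease=config.true_disrupt_rate_disease,
        priors=priors,
    )
    return common, disease, truth


def generate_bundle(config: GeneratorConfig, priors: PriorSet | None = None) -> Bundle:
    """The complete synthetic input bundle for one seed."""
    interactome, chain_models = generate_interactome(config)
    experiments, promoter_ids, _ = generate_expression(config, interactome)
    common, disease, truth = generate_mutations(config, interactome, priors)
    return Bundle(
        interactome=interactome,
        chain_models=chain_models,
        experiments=experiments,
        promoter_experiment_ids=promoter_ids,
        common=common,
        disease=disease,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Bundle round-trip through the external file formats
# ---------------------------------------------------------------------------

def write_bundle(bundle: Bundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.interactome.proteins.values(), out / "proteins.fasta")
    write_interactome_tsv(bundle.interactome, out / "interactome.tsv")
    manifest = []
    for exp in bundle.experiments:
        fname = f"expr_{exp.experiment_id}.tsv"
        write_expression_tsv(exp, out / fname)
        manifest.append((exp.experiment_id, exp.kind, fname))
    write_manifest_tsv(manifest, out / "manifest.tsv")
    with open(out / "promoter_sources.txt", "w") as fh:
        for exp_id in bundle.promoter_experiment_ids:
            fh.write(exp_id + "\n")
    write_mutations_tsv(bundle.common, out / "common_mutations.tsv")
    write_mutations_tsv(bundle.disease, out / "disease_mutations.tsv")
    write_effects_tsv(list(bundle.common) + list(bundle.disease), out / "ddg_effects.tsv")


def read_bundle(out_dir: str | Path, name: str = "interactome") -> Bundle:
    out = Path(out_dir)
    proteins = read_fasta(out / "proteins.fasta")
    interactome = read_interactome_tsv(out / "interactome.tsv", proteins, name=name)
    experiments = [
        read_expression_tsv(out / fname, exp_id, kind)
        for exp_id, kind, fname in read_manifest_tsv(out / "manifest.tsv")
    ]
    promoter_ids = tuple(
        line.strip()
        for line in (out / "promoter_sources.txt").read_text().splitlines()
        if line.strip()
    )
    common = read_mutations_tsv(out / "common_mutations.tsv")
    disease = read_mutations_tsv(out / "disease_mutations.tsv")
    attach_effects_tsv(common + disease, out / "ddg_effects.tsv")
    truth = GroundTruth(
        disruption_target={}, rate_common=float("nan"), rate_disease=float("nan"),
        priors=PriorSet(),
    )
    return Bundle(
        interactome=interactome,
        chain_models={},
        experiments=experiments,
        promoter_experiment_ids=promoter_ids,
        common=common,
        disease=disease,
        truth=truth,
    )
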