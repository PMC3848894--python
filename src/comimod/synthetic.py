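"""Self-contained synthetic cohorts with planted discriminative modules.

The generator emulates the data-generating assumption behind the method:
several miRNAs co-regulate one biological process, and in bad-outcome
patients the expression of their target genes inside that process is
repressed relative to the term's non-targets.  Concretely, background
expression is i.i.d. Normal(baseline, sd^2); each planted module is a GO
term plus a set of member miRNAs whose constructed in-term target blocks are
shifted by -effect_size * noise_sd in bad-outcome samples only.  Non-planted
terms get member miRNAs with equally constructed (significant) in-term
target blocks but no expression shift, so false module selection is
measurable.

All miRNA-term intersections that are meant to survive the pair filters are
constructed, not left to chance: blocks are disjoint within a term and sized
so that the intersection passes both the minimum-overlap and the
hypergeometric significance screens.

On top of the i.i.d. gene noise, every term carries a per-sample random
offset (sd ``term_offset_sd``) shared by all of its genes.  The offset
cancels exactly in the within-term target-vs-non-target contrast that the
CoMi score measures, but inflates the marginal variance of every annotated
gene: the planted signal is therefore efficiently detectable as a within-term
contrast and only weakly as a marginal gene effect, which is the regime the
module method is designed for.

Planted terms occupy disjoint gene strata, and background terms draw from a
separate gene pool.  Because the class-dependent shift is applied to genes,
any term sharing genes with a planted term would inherit a fixed
target-vs-non-target imbalance and stop being a null module; stratifying the
gene space keeps "planted" and "null" well-defined so that false module
selection is actually measurable.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (
    BAD,
    GOOD,
    GeneSetCollection,
    write_expression,
    write_gmt,
    write_labels,
)
from .errors import DataError


@dataclass
class SyntheticConfig:
    """Knobs of the cohort simulator; defaults give the reference cohort
    (8 planted modules of 6 miRNAs among 40 terms, effect 1.5 sd, 100
    samples per class)."""

    n_genes: int = 3000
    n_mirnas: int = 112
    n_terms: int = 40
    term_size: tuple[int, int] = (110, 130)
    targets_per_mirna: tuple[int, int] = (50, 70)
    n_planted_modules: int = 8
    mirnas_per_module: int = 6
    planted_intersection: int = 12
    n_pos: int = 100
    n_neg: int = 100
    effect_size: float = 1.5
    noise_sd: float = 1.0
    term_offset_sd: float = 2.0
    baseline_mean: float = 7.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genes, self.n_mirnas, self.n_terms, self.n_pos, self.n_neg,
               self.mirnas_per_module, self.planted_intersection) <= 0:
            raise DataError("all synthetic counts must be positive")
        if self.n_planted_modules < 0 or self.n_planted_modules > self.n_terms:
            raise DataError("n_planted_modules must be between 0 and n_terms")
        if self.term_size[0] > self.term_size[1] or self.term_size[1] > self.n_genes:
            raise DataError("invalid term_size range")
        n_background_pool = self.n_genes - self.n_planted_modules * self.term_size[1]
        if self.n_terms > self.n_planted_modules and n_background_pool < self.term_size[1]:
            raise DataError(
                "n_genes too small: planted strata leave no gene pool for background terms"
            )
        if self.targets_per_mirna[0] > self.targets_per_mirna[1]:
            raise DataError("invalid targets_per_mirna range")
        if self.targets_per_mirna[1] > self.n_genes:
            raise DataError("targets_per_mirna exceeds n_genes")
        if self.mirnas_per_module * self.planted_intersection > self.term_size[0]:
            raise DataError(
                "term_size too small for disjoint member target blocks "
                f"({self.mirnas_per_module} x {self.planted_intersection} > {self.term_size[0]})"
            )
        n_dedicated = self.n_planted_modules * self.mirnas_per_module
        pool = self.n_mirnas - n_dedicated
        n_background_terms = self.n_terms - self.n_planted_modules
        if n_background_terms > 0:
            if pool < self.mirnas_per_module:
                raise DataError("not enough background miRNAs for non-planted modules")
            load = ceil(n_background_terms * self.mirnas_per_module / pool)
            if load * self.planted_intersection > self.targets_per_mirna[0]:
                raise DataError(
                    "targets_per_mirna too small for the background miRNA load "
                    f"({load} terms x {self.planted_intersection} forced targets)"
                )
        if self.noise_sd <= 0:
            raise DataError("noise_sd must be positive")
        if self.term_offset_sd < 0:
            raise DataError("term_offset_sd must be nonnegative")


@dataclass
class SyntheticCohort:
    expr: pd.DataFrame
    targets: GeneSetCollection
    gobp: GeneSetCollection
    labels: pd.Series
    planted_module_ids: list[str] = field(default_factory=list)


@dataclass
class _Structure:
    genes: list[str]
    mirnas: list[str]
    terms: GeneSetCollection
    targets: GeneSetCollection
    planted_term_ids: list[str]
    shifted_genes: list[str]


def _build_structure(config: SyntheticConfig, rng: np.random.Generator) -> _Structure:
    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    mirnas = [f"mir-{i + 1:03d}" for i in range(config.n_mirnas)]
    term_ids = [f"GO:{i + 1:07d}" for i in range(config.n_terms)]

    planted = [term_ids[i] for i in sorted(
        rng.choice(config.n_terms, size=config.n_planted_modules, replace=False))]
    planted_set = set(planted)

    # planted terms occupy disjoint strata of a shuffled gene list; background
    # terms sample from the remaining pool (see module docstring)
    perm = list(rng.permutation(config.n_genes))
    terms = GeneSetCollection()
    term_members: dict[str, list[str]] = {}
    cursor = 0
    for tid in planted:
        size = int(rng.integers(config.term_size[0], config.term_size[1] + 1))
        term_members[tid] = [genes[i] for i in perm[cursor:cursor + size]]
        cursor += size
    background_pool = perm[cursor:]
    for tid in term_ids:
        if tid in planted_set:
            continue
        size = int(rng.integers(config.term_size[0], config.term_size[1] + 1))
        members = rng.choice(len(background_pool), size=size, replace=False)
        term_members[tid] = [genes[background_pool[i]] for i in members]
    for tid in term_ids:
        terms.add(tid, term_members[tid], f"synthetic biological process {tid}")

    # membership: planted terms take dedicated miRNAs, background terms share a pool
    n_dedicated = config.n_planted_modules * config.mirnas_per_module
    membership: dict[str, list[str]] = {m: [] for m in mirnas}
    it = iter(mirnas[:n_dedicated])
    for tid in planted:
        for _ in range(config.mirnas_per_module):
            membership[next(it)].append(tid)
    pool = mirnas[n_dedicated:]
    background_terms = [t for t in term_ids if t not in set(planted)]
    if background_terms and pool:
        pool = list(rng.permutation(pool))
        slot = 0
        for tid in background_terms:
            for _ in range(config.mirnas_per_module):
                membership[pool[slot % len(pool)]].append(tid)
                slot += 1

    # disjoint forced target blocks within each term, one per member miRNA
    members_of_term: dict[str, list[str]] = {t: [] for t in term_ids}
    for m, tlist in membership.items():
        for t in tlist:
            members_of_term[t].append(m)
    forced: dict[str, set[str]] = {m: set() for m in mirnas}
    forced_in_term: dict[str, dict[str, list[str]]] = {}
    for tid in term_ids:
        shuffled = list(rng.permutation(term_members[tid]))
        blocks = {}
        for j, m in enumerate(members_of_term[tid]):
            block = shuffled[j * config.planted_intersection:(j + 1) * config.planted_intersection]
            blocks[m] = block
            forced[m].update(block)
        forced_in_term[tid] = blocks

    # fill each miRNA's targets with genes outside all its member terms
    targets = GeneSetCollection()
    gene_set = set(genes)
    for m in mirnas:
        k_total = int(rng.integers(config.targets_per_mirna[0], config.targets_per_mirna[1] + 1))
        member_genes: set[str] = set()
        for t in membership[m]:
            member_genes.update(term_members[t])
        outside = sorted(gene_set - member_genes - forced[m])
        n_fill = max(0, k_total - len(forced[m]))
        n_fill = min(n_fill, len(outside))
        fill = [outside[i] for i in rng.choice(len(outside), size=n_fill, replace=False)]
        targets.add(m, sorted(forced[m]) + fill, "synthetic miRNA target set")

    shifted: set[str] = set()
    for tid in planted:
        for block in forced_in_term[tid].values():
            shifted.update(block)
    return _Structure(
        genes=genes,
        mirnas=mirnas,
        terms=terms,
        targets=targets,
        planted_term_ids=planted,
        shifted_genes=sorted(shifted),
    )


def _draw_expression(
    structure: _Structure,
    config: SyntheticConfig,
    rng: np.random.Generator,
    n_pos: int,
    n_neg: int,
    sample_prefix: str,
) -> tuple[pd.DataFrame, pd.Series]:
    n_samples = n_pos + n_neg
    sample_ids = [f"{sample_prefix}{i + 1:04d}" for i in range(n_samples)]
    labels = pd.Series(
        np.concatenate([np.full(n_pos, GOOD), np.full(n_neg, BAD)]).astype("int8"),
        index=sample_ids,
        name="label",
    )
    X = rng.normal(config.baseline_mean, config.noise_sd,
                   size=(config.n_genes, n_samples))
    row_of = {g: i for i, g in enumerate(structure.genes)}
    if config.term_offset_sd > 0:
        # per-sample term-level offset shared by the whole term (cancels in
        # the within-term CoMi contrast, masks marginal gene effects)
        for tid in structure.terms:
            rows = [row_of[g] for g in structure.terms.members(tid)]
            X[rows] += rng.normal(0.0, config.term_offset_sd, size=n_samples)[None, :]
    if structure.shifted_genes:
        bad_cols = np.flatnonzero(labels.to_numpy() == BAD)
        rows = [row_of[g] for g in structure.shifted_genes]
        X[np.ix_(rows, bad_cols)] -= config.effect_size * config.noise_sd
    expr = pd.DataFrame(X, index=pd.Index(structure.genes, name="gene_id"),
                        columns=sample_ids)
    return expr, labels


def generate(config: SyntheticConfig) -> SyntheticCohort:
    """Generate one cohort; fully determined by ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    structure = _build_structure(config, rng)
    expr, labels = _draw_expression(structure, config, rng, config.n_pos, config.n_neg, "s")
    return SyntheticCohort(
        expr=expr,
        targets=structure.targets,
        gobp=structure.terms,
        labels=labels,
        planted_module_ids=list(structure.planted_term_ids),
    )


def generate_train_test(
    config: SyntheticConfig,
    n_test_pos: int = 50,
    n_test_neg: int = 50,
) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Train and held-out cohorts sharing one planted structure.

    Gene sets and planted modules are identical; only the expression noise
    (and hence the CoMi scores) is drawn independently for the two cohorts.
    """
    config.validate()
    if n_test_pos <= 0 or n_test_neg <= 0:
        raise DataError("test class sizes must be positive")
    rng = np.random.default_rng(config.seed)
    structure = _build_structure(config, rng)
    expr_tr, y_tr = _draw_expression(structure, config, rng, config.n_pos, config.n_neg, "s")
    expr_te, y_te = _draw_expression(structure, config, rng, n_test_pos, n_test_neg, "t")
    train = SyntheticCohort(expr_tr, structure.targets, structure.terms, y_tr,
                            list(structure.planted_term_ids))
    test = SyntheticCohort(expr_te, structure.targets, structure.terms, y_te,
                           list(structure.planted_term_ids))
    return train, test


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Emit expr.tsv, targets.gmt, gobp.gmt, labels.tsv and planted.txt."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expr": outdir / "expr.tsv",
        "targets": outdir / "targets.gmt",
        "gobp": outdir / "gobp.gmt",
        "labels": outdir / "labels.tsv",
        "planted": outdir / "planted.txt",
    }
    write_expression(cohort.expr, paths["expr"])
    write_gmt(cohort.targets, paths["targets"])
    write_gmt(cohort.gobp, paths["gobp"])
    write_labels(cohort.labels, paths["labels"])
    paths["planted"].write_text("".join(f"{t}\n" for t in cohort.planted_module_ids))
    return paths


def config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["term_size"] = list(d["term_size"])
    d["targets_per_mirna"] = list(d["targets_per_mirna"])
    return d


def config_from_dict(d: dict) -> SyntheticConfig:
    d = dict(d)
    for key in ("term_size", "targets_per_mirna"):
        if key in d:
            d[key] = tuple(d[key])
    return SyntheticConfig(**d)
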