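"""Synthetic two-species chromatin datasets with planted ground truth.

The generator emulates the salient features of expression-coupled histone
modification landscapes in budding yeast:

* H3K9ac emission concentrated at the +1 nucleosome (with a -1 promoter
  contribution at a fraction of genes), sharply declining downstream;
* H3K4me3 plateauing over the +2/+3 nucleosomes and decaying thereafter;
* H3 occupancy dipping at the promoter (-1) relative to the ORF;
* per-gene modification amplitudes scaling multiplicatively with 2^expr;
* a planted acetylation/methylation disparity at OPN and DPN genes;
* a second species whose expression diverges by Normal(0, divergence_sd_expr)
  per ortholog, with H3K4me3 divergence tracking the expression shift with
  weight ``k4_expr_coupling`` and H3K9ac with weight ``k9_expr_coupling``.

Reads are single-end: fragments of constant length are sampled with
midpoints uniform within a nucleosome chosen proportionally to its
emission intensity; each fragment emits a forward read at its start and a
reverse read at its last base, each with probability 0.5.

Every generator is a pure function of (config, seed); no distributional
choice here is fitted to real data -- they are stand-ins that exercise the
estimators downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from chromdiverge.io import GeneModel, NucleosomeRecord

#: Nucleosome spacing from the TSS; +1 starts at the TSS.
NUCLEOSOME_SPACING = 165
#: Gene-relative nucleosome indices generated for every gene.
NUC_INDICES = (-2, -1, 1, 2, 3, 4, 5, 6)

#: Relative per-nucleosome emission shapes (linear scale, before the
#: expression-coupled amplitude).  Acetylation peaks at +1, methylation
#: plateaus over +2/+3, H3 occupancy dips at the -1 / promoter.
SHAPE_AC = {-2: 0.10, -1: 0.12, 1: 1.00, 2: 0.35, 3: 0.15, 4: 0.08, 5: 0.05, 6: 0.04}
SHAPE_AC_MINUS1 = 0.60  # -1 emission at the "promoter-acetylated" subset
SHAPE_ME = {-2: 0.05, -1: 0.08, 1: 0.45, 2: 1.00, 3: 1.00, 4: 0.55, 5: 0.30, 6: 0.18}
SHAPE_H3 = {-2: 0.70, -1: 0.45, 1: 0.90, 2: 1.00, 3: 1.00, 4: 1.00, 5: 1.00, 6: 1.00}

MARKS = ("H3K9ac", "H3K4me3", "H3")


def _default_class_fractions() -> dict[str, float]:
    return {
        "OPN": 0.25,
        "DPN": 0.25,
        "TATA": 0.20,
        "essential": 0.20,
        "periodic": 0.15,
        "responsive": 0.20,
        "non_responsive": 0.20,
    }


@dataclass
class SimulationConfig:
    """All knobs of the synthetic dataset; defaults are the study conditions."""

    n_genes: int = 2000
    n_chroms: int = 4
    chrom_len: int | None = None  # None: auto-sized to fit the genes
    gene_spacing: int = 900
    gene_len_min: int = 800
    gene_len_max: int = 2200
    margin: int = 700
    fragment_length: int = 150
    read_length: int = 40
    reads_per_sample: int = 1_000_000
    rna_depth: int = 2_000_000
    expression_mean: float = 4.0
    expression_log_sd: float = 1.0
    mark_log_sd: float = 0.6  # gene-level log2 noise per mark, independent of expr
    disparity_effect: float = 1.0  # log2 added to ac at OPN genes / me at DPN genes
    ac_minus1_fraction: float = 0.3
    divergence_sd_expr: float = 0.6
    divergence_sd_mod: float = 0.5
    k4_expr_coupling: float = 0.8
    k9_expr_coupling: float = 0.1
    ortholog_fraction: float = 0.9
    n_conditions: int = 200
    sd_responsive: float = 2.0
    sd_non_responsive: float = 0.2
    sd_background: float = 0.8
    class_fractions: dict[str, float] = field(default_factory=_default_class_fractions)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_chroms", "gene_spacing", "fragment_length",
                     "read_length", "reads_per_sample", "rna_depth", "n_conditions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("k4_expr_coupling", "k9_expr_coupling", "ortholog_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.class_fractions.get("OPN", 0) + self.class_fractions.get("DPN", 0) > 1:
            raise ValueError("OPN + DPN fractions exceed 1 (classes are disjoint)")

    def rng(self, stage: int) -> np.random.Generator:
        """Deterministic per-stage generator derived from the config seed."""
        return np.random.default_rng([int(self.seed) % (2**31), stage])


@dataclass
class TruthLandscape:
    """Planted ground truth for one species.

    ``expression`` is log2 expression per gene; ``intensity[mark]`` is a
    genes x nucleosome-index DataFrame of nonnegative linear emission
    intensities.
    """

    species: str
    expression: pd.Series
    intensity: dict[str, pd.DataFrame]


@dataclass
class Genomes:
    annotation_a: list[GeneModel]
    annotation_b: list[GeneModel]
    nucleosomes_a: list[NucleosomeRecord]
    nucleosomes_b: list[NucleosomeRecord]
    orthologs: pd.DataFrame  # gene_id_a, gene_id_b
    classes: pd.DataFrame  # gene_id, class_name (species A ids)
    chrom_sizes: dict[str, int]


# ---------------------------------------------------------------------------
# genome architecture


def _nucleosome_interval(gene: GeneModel, index: int) -> tuple[int, int]:
    """Genomic half-open interval of nucleosome ``index`` for a gene.

    Transcription-relative offsets: +i covers [(i-1)*S, i*S), -j covers
    [-j*S, -(j-1)*S), with S the nucleosome spacing.
    """
    s = NUCLEOSOME_SPACING
    if index > 0:
        r0, r1 = (index - 1) * s, index * s
    else:
        r0, r1 = index * s, (index + 1) * s
    if gene.strand == "+":
        return gene.tss + r0, gene.tss + r1
    return gene.tss - r1 + 1, gene.tss - r0 + 1


def generate_genomes(config: SimulationConfig) -> Genomes:
    """Lay out two species' annotations, nucleosome maps, orthologs, classes.

    Both species share gene architecture (orthologous genes sit at the same
    coordinates with the same nucleosome layout); ids are ``gA####`` /
    ``gB####``.  A configured fraction of genes (default 0.9) enters the
    one-to-one ortholog map.  Class labels are drawn per ``class_fractions``
    with OPN/DPN, TATA/Tless and responsive/non-responsive kept disjoint.
    """
    config.validate()
    rng = config.rng(stage=1)

    per_chrom = -(-config.n_genes // config.n_chroms)  # ceil
    lengths = rng.integers(config.gene_len_min, config.gene_len_max + 1,
                           size=config.n_genes)
    strands = rng.choice(["+", "-"], size=config.n_genes)

    footprint = config.gene_len_max + config.gene_spacing
    needed = 2 * config.margin + per_chrom * footprint
    chrom_len = config.chrom_len if config.chrom_len is not None else needed
    if chrom_len < needed:
        raise ValueError(
            f"chrom_len {chrom_len} cannot fit {per_chrom} genes without overlap "
            f"(need >= {needed})"
        )

    genes_a: list[GeneModel] = []
    chrom_sizes: dict[str, int] = {}
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        chrom_sizes[chrom] = chrom_len
        cursor = config.margin
        for gi in range(ci * per_chrom, min((ci + 1) * per_chrom, config.n_genes)):
            length = int(lengths[gi])
            a = cursor
            if strands[gi] == "+":
                gene = GeneModel(f"gA{gi:04d}", chrom, "+", a, a + length)
            else:
                gene = GeneModel(f"gA{gi:04d}", chrom, "-", a + length - 1, a - 1)
            genes_a.append(gene)
            cursor += footprint

    # species B mirrors the architecture under its own ids
    genes_b = [
        GeneModel("gB" + g.gene_id[2:], g.chrom, g.strand, g.tss, g.tts)
        for g in genes_a
    ]

    nucs_a = [
        NucleosomeRecord(g.gene_id, idx, g.chrom, *_nucleosome_interval(g, idx))
        for g in genes_a
        for idx in NUC_INDICES
    ]
    nucs_b = [
        NucleosomeRecord(g.gene_id, idx, g.chrom, *_nucleosome_interval(g, idx))
        for g in genes_b
        for idx in NUC_INDICES
    ]

    is_orth = rng.random(config.n_genes) < config.ortholog_fraction
    orthologs = pd.DataFrame(
        {
            "gene_id_a": [g.gene_id for g, o in zip(genes_a, is_orth) if o],
            "gene_id_b": [g.gene_id for g, o in zip(genes_b, is_orth) if o],
        }
    )

    classes = _draw_classes(config, [g.gene_id for g in genes_a], rng)
    return Genomes(genes_a, genes_b, nucs_a, nucs_b, orthologs, classes, chrom_sizes)


def _draw_classes(config: SimulationConfig, gene_ids: list[str],
                  rng: np.random.Generator) -> pd.DataFrame:
    fr = config.class_fractions
    n = len(gene_ids)
    ids = np.asarray(gene_ids)
    rows: list[tuple[str, str]] = []

    def take_disjoint(name_a: str, name_b: str) -> None:
        fa, fb = fr.get(name_a, 0.0), fr.get(name_b, 0.0)
        perm = rng.permutation(n)
        na, nb = int(round(fa * n)), int(round(fb * n))
        rows.extend((ids[i], name_a) for i in perm[:na])
        rows.extend((ids[i], name_b) for i in perm[na:na + nb])

    take_disjoint("OPN", "DPN")
    take_disjoint("TATA", "Tless")
    take_disjoint("responsive", "non_responsive")
    for name in ("essential", "periodic"):
        f = fr.get(name, 0.0)
        mask = rng.random(n) < f
        rows.extend((gid, name) for gid, m in zip(ids, mask) if m)
    return pd.DataFrame(rows, columns=["gene_id", "class_name"])


# ---------------------------------------------------------------------------
# planted landscapes


def plant_landscapes(
    genomes: Genomes, config: SimulationConfig
) -> tuple[TruthLandscape, TruthLandscape]:
    """Plant per-gene, per-nucleosome emission intensities for both species.

    Species A: intensity[mark][gene, nuc] = shape[mark][nuc] *
    2^(expr + class effect + gene-level mark noise).  Species B keeps the
    same architecture; its expression shifts by Normal(0, divergence_sd_expr)
    per ortholog-shared gene, and each mark's amplitude follows that shift
    with its coupling weight: delta_mark = k * delta_expr +
    (1 - k) * Normal(0, divergence_sd_mod).  With k = 1 the planted mark
    divergence equals the expression divergence exactly; with k = 0 it is
    independent of it.
    """
    rng = config.rng(stage=2)
    ids = pd.Index([g.gene_id for g in genomes.annotation_a], name="gene_id")
    n = len(ids)

    expr_a = pd.Series(
        rng.normal(config.expression_mean, config.expression_log_sd, n), index=ids
    )
    noise_ac = rng.normal(0.0, config.mark_log_sd, n)
    noise_me = rng.normal(0.0, config.mark_log_sd, n)
    noise_h3 = rng.normal(0.0, 0.2, n)

    class_sets = {
        name: set(sub["gene_id"])
        for name, sub in genomes.classes.groupby("class_name")
    }
    in_opn = ids.isin(class_sets.get("OPN", set())).astype(float)
    in_dpn = ids.isin(class_sets.get("DPN", set())).astype(float)
    minus1 = (rng.random(n) < config.ac_minus1_fraction)

    amp_ac = expr_a.to_numpy() + noise_ac + config.disparity_effect * in_opn
    amp_me = expr_a.to_numpy() + noise_me + config.disparity_effect * in_dpn

    def build(shapes: Mapping[int, float], amp_log2: np.ndarray,
              minus1_boost: bool = False) -> pd.DataFrame:
        mat = np.empty((n, len(NUC_INDICES)))
        for j, idx in enumerate(NUC_INDICES):
            base = np.full(n, shapes[idx])
            if minus1_boost and idx == -1:
                base = np.where(minus1, SHAPE_AC_MINUS1, base)
            mat[:, j] = base * np.exp2(amp_log2)
        return pd.DataFrame(mat, index=ids, columns=list(NUC_INDICES))

    land_a = TruthLandscape(
        species="A",
        expression=expr_a,
        intensity={
            "H3K9ac": build(SHAPE_AC, amp_ac, minus1_boost=True),
            "H3K4me3": build(SHAPE_ME, amp_me),
            "H3": build(SHAPE_H3, noise_h3),
        },
    )

    d_expr = rng.normal(0.0, config.divergence_sd_expr, n)
    eta_me = rng.normal(0.0, config.divergence_sd_mod, n)
    eta_ac = rng.normal(0.0, config.divergence_sd_mod, n)
    d_me = config.k4_expr_coupling * d_expr + (1 - config.k4_expr_coupling) * eta_me
    d_ac = config.k9_expr_coupling * d_expr + (1 - config.k9_expr_coupling) * eta_ac
    d_h3 = rng.normal(0.0, 0.1, n)

    ids_b = pd.Index(["gB" + gid[2:] for gid in ids], name="gene_id")
    expr_b = pd.Series(expr_a.to_numpy() + d_expr, index=ids_b)
    land_b = TruthLandscape(
        species="B",
        expression=expr_b,
        intensity={
            "H3K9ac": build(SHAPE_AC, amp_ac + d_ac, minus1_boost=True).set_axis(ids_b),
            "H3K4me3": build(SHAPE_ME, amp_me + d_me).set_axis(ids_b),
            "H3": build(SHAPE_H3, noise_h3 + d_h3).set_axis(ids_b),
        },
    )
    return land_a, land_b


# ---------------------------------------------------------------------------
# read simulation


def simulate_chip_reads(
    landscape: TruthLandscape,
    mark: str,
    nucleosomes: list[NucleosomeRecord],
    chrom_sizes: dict[str, int],
    config: SimulationConfig,
    stage: int = 3,
) -> pd.DataFrame:
    """Sample single-end ChIP reads for one mark of one species.

    Fragment midpoints are drawn proportionally to nucleosome emission
    intensity (uniform within the nucleosome interval); fragments have
    constant length ``config.fragment_length``.  Each fragment emits a
    forward read at its start and a reverse read at its last base, each
    with probability 0.5.  Returns a DataFrame with columns
    chrom / pos / strand (pos = first sequenced base).
    """
    rng = config.rng(stage=stage)
    inten = landscape.intensity[mark]

    starts, ends, weights, chrom_codes = [], [], [], []
    chrom_names = list(chrom_sizes)
    chrom_index = {c: i for i, c in enumerate(chrom_names)}
    for rec in nucleosomes:
        w = inten.at[rec.gene_id, rec.index] if rec.gene_id in inten.index else 0.0
        starts.append(rec.start)
        ends.append(rec.end)
        weights.append(w)
        chrom_codes.append(chrom_index[rec.chrom])
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    weights = np.asarray(weights, dtype=float)
    chrom_codes = np.asarray(chrom_codes)

    total = weights.sum()
    if total <= 0:
        raise ValueError(f"zero total emission intensity for mark {mark!r}")

    counts = rng.multinomial(config.reads_per_sample, weights / total)
    cell = np.repeat(np.arange(len(weights)), counts)
    mid = starts[cell] + rng.random(cell.size) * (ends[cell] - starts[cell])
    frag_start = np.floor(mid).astype(np.int64) - config.fragment_length // 2
    frag_last = frag_start + config.fragment_length - 1
    cc = chrom_codes[cell]
    lens = np.asarray([chrom_sizes[c] for c in chrom_names])

    emit_f = rng.random(cell.size) < 0.5
    emit_r = rng.random(cell.size) < 0.5
    ok_f = emit_f & (frag_start >= 0) & (frag_start < lens[cc])
    ok_r = emit_r & (frag_last >= 0) & (frag_last < lens[cc])

    chroms = np.asarray(chrom_names, dtype=object)
    df = pd.DataFrame(
        {
            "chrom": np.concatenate([chroms[cc[ok_f]], chroms[cc[ok_r]]]),
            "pos": np.concatenate([frag_start[ok_f], frag_last[ok_r]]),
            "strand": np.concatenate(
                [np.full(ok_f.sum(), "+", dtype=object),
                 np.full(ok_r.sum(), "-", dtype=object)]
            ),
        }
    )
    return df


def simulate_expression_counts(
    landscape: TruthLandscape,
    annotation: list[GeneModel],
    config: SimulationConfig,
    n_replicates: int = 2,
    stage: int = 6,
) -> pd.DataFrame:
    """Poisson RNA-seq counts per gene per replicate.

    lambda_g = depth * L_g * 2^expr_g / sum_g(L_g * 2^expr_g); replicates
    draw independent noise.
    """
    rng = config.rng(stage=stage)
    ids = [g.gene_id for g in annotation]
    lengths = np.asarray([g.length for g in annotation], dtype=float)
    expr = landscape.expression.reindex(ids).to_numpy()
    weight = lengths * np.exp2(expr)
    lam = config.rna_depth * weight / weight.sum()
    counts = {
        f"rep{r + 1}": rng.poisson(lam) for r in range(n_replicates)
    }
    return pd.DataFrame(counts, index=pd.Index(ids, name="gene_id"))


def generate_compendium(
    landscape: TruthLandscape,
    classes: pd.DataFrame,
    config: SimulationConfig,
    stage: int = 7,
) -> pd.DataFrame:
    """Conditions x genes expression compendium with planted responsiveness.

    Responsive genes fluctuate with SD ``sd_responsive`` across conditions,
    non-responsive with ``sd_non_responsive``, everything else with
    ``sd_background``; values are log-scale expression centred on each
    gene's baseline.
    """
    rng = config.rng(stage=stage)
    ids = landscape.expression.index
    sets = {name: set(sub["gene_id"]) for name, sub in classes.groupby("class_name")}
    sd = np.full(len(ids), config.sd_background)
    sd[ids.isin(sets.get("responsive", set()))] = config.sd_responsive
    sd[ids.isin(sets.get("non_responsive", set()))] = config.sd_non_responsive
    base = landscape.expression.to_numpy()
    values = base + rng.normal(0.0, 1.0, (config.n_conditions, len(ids))) * sd
    return pd.DataFrame(
        values,
        index=pd.Index([f"cond{i:03d}" for i in range(config.n_conditions)],
                       name="condition"),
        columns=ids,
    )


# ---------------------------------------------------------------------------
# one-call dataset


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genomes: Genomes
    landscape_a: TruthLandscape
    landscape_b: TruthLandscape
    chip_reads: dict[tuple[str, str], pd.DataFrame]  # (species, mark) -> reads
    rna_counts: dict[str, pd.DataFrame]  # species -> genes x replicates
    compendium: pd.DataFrame


def simulate_dataset(config: SimulationConfig,
                     marks: tuple[str, ...] = MARKS) -> SimulatedDataset:
    """Generate the full two-species dataset in one call (pure in config)."""
    genomes = generate_genomes(config)
    land_a, land_b = plant_landscapes(genomes, config)
    chip: dict[tuple[str, str], pd.DataFrame] = {}
    stage = 10
    for species, land, nucs in (
        ("A", land_a, genomes.nucleosomes_a),
        ("B", land_b, genomes.nucleosomes_b),
    ):
        for mark in marks:
            chip[(species, mark)] = simulate_chip_reads(
                land, mark, nucs, genomes.chrom_sizes, config, stage=stage
            )
            stage += 1
    rna = {
        "A": simulate_expression_counts(land_a, genomes.annotation_a, config, stage=30),
        "B": simulate_expression_counts(land_b, genomes.annotation_b, config, stage=31),
    }
    compendium = generate_compendium(land_a, genomes.classes, config)
    return SimulatedDataset(config, genomes, land_a, land_b, chip, rna, compendium)


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)


def config_from_dict(d: Mapping) -> SimulationConfig:
    return SimulationConfig(**dict(d))
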