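"""Synthetic inputs with the statistical structure the pipeline assumes.

Everything the analysis consumes can be generated here at desk scale: a toy
genome with planted genes and regulatory elements, strand-specific PRO-seq
style tracks with divergent promoter-proximal pausing, a smooth
accessibility target for the imputation stage, negative-binomial feature
count tables with planted fold changes, random TRE sequences with optional
planted motifs, and expression cohorts with heavy right tails for the four
RET-ligand genes.

All randomness flows from one integer seed through named
``numpy.random.SeedSequence`` children, so sub-generators are independent
and every output is bit-identical across runs for a fixed seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ligandscore import LIGAND_GENES, RECEPTOR_GENES, ExpressionCohort
from .tracks import GeneAnnotation, Interval, StrandTracks

__all__ = [
    "SimParams",
    "ToyGenome",
    "PackingError",
    "gen_genome",
    "gen_proseq_tracks",
    "gen_accessibility_truth",
    "gen_count_table",
    "gen_expression_cohort",
    "gen_tre_sequences",
    "background_windows",
    "write_genome_beds",
    "child_rng",
]


class PackingError(ValueError):
    """Requested features cannot be packed into the chromosome."""


def child_rng(seed: int, *tags: str) -> np.random.Generator:
    """Derive an independent generator from (seed, tag path).

    Tags are hashed with CRC32 so derivation is stable across interpreter
    runs (unlike Python's randomized str hash).
    """
    key = tuple(zlib.crc32(t.encode()) for t in tags)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the synthetic genome and cohort.

    Rates are expected reads per base; ``planted_fc`` is in log2 units and is
    the magnitude applied to differential features; ``ligand_tail_fraction``
    is the fraction of cohort samples planted in the high-expression tail of
    at least one RET ligand; ``responder_shift`` is the additive increase in
    a non-responder's expected number of ligand tail memberships.
    """

    seed: int = 0
    chrom_length: int = 1_000_000
    n_genes: int = 50
    n_tres: int = 30  # enhancers; every gene additionally gets a promoter TRE
    gene_length_range: tuple[int, int] = (3_000, 8_000)
    tre_width: int = 300
    pause_height: float = 2.0
    body_density: float = 0.05
    enhancer_height: float = 1.0
    nb_dispersion: float = 0.02
    planted_fc: float = 2.0
    diff_fraction: float = 0.2
    ligand_tail_fraction: float = 0.13
    responder_shift: float = 0.5
    n_cohort_samples: int = 925
    n_cohort_genes: int = 30
    ligand_scale: float = 5.0
    ligand_baseline_sigma: float = 0.5
    ligand_tail_shift: float = 1.0
    ligand_tail_sigma: float = 0.3
    receptor_esr1_rho: float = 0.5
    er_positive_fraction: float = 0.79

    def __post_init__(self) -> None:
        for name in ("pause_height", "body_density", "enhancer_height"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0 <= self.ligand_tail_fraction < 0.5:
            raise ValueError("ligand_tail_fraction must lie in [0, 0.5)")
        if self.responder_shift < 0:
            raise ValueError("responder_shift must be non-negative")
        if self.gene_length_range[0] < 2_000:
            raise ValueError("genes must be at least 2,000 bp")


@dataclass
class ToyGenome:
    """A packed toy genome: genes, true TREs, and planted fold changes."""

    chrom_sizes: dict[str, int]
    genes: list[GeneAnnotation]
    true_tres: list[dict]  # interval, class in {promoter, enhancer}, active flag
    differential_truth: dict[str, float]  # feature id -> planted log2 fold change
    pause_geometry: dict[str, tuple[int, int]] = field(default_factory=dict)

    def tre_intervals(self) -> list[Interval]:
        return [t["interval"] for t in self.true_tres]


_MARGIN = 400  # enforced gap between packed features, bp


def _pack_intervals(rng, total_len: int, lengths: list[int]) -> list[int]:
    """Place intervals of given lengths without overlap, uniformly at random.

    Stars-and-bars placement: each feature is padded by a fixed margin, the
    remaining free space is split by a sorted uniform draw.  Raises
    :class:`PackingError` when the features cannot fit.
    """
    n = len(lengths)
    if n == 0:
        return []
    padded = [l + _MARGIN for l in lengths]
    free = total_len - sum(padded)
    if free <= n:
        raise PackingError(
            f"cannot pack {n} features totalling {sum(lengths)} bp "
            f"(+margins) into {total_len} bp"
        )
    cuts = np.sort(rng.choice(free, size=n, replace=False))
    starts = []
    offset = _MARGIN // 2
    for i, length in enumerate(padded):
        starts.append(int(cuts[i]) + offset)
        offset += length
    return starts


def gen_genome(params: SimParams) -> ToyGenome:
    """Build a toy genome with non-overlapping genes and planted TREs.

    Every gene carries a promoter TRE centered on its TSS; enhancer TREs go
    into intergenic space.  A ``diff_fraction`` of genes and of TREs get a
    planted log2 fold change of ±``planted_fc`` (balanced signs).
    Deterministic for a fixed seed.
    """
    rng = child_rng(params.seed, "genome")
    chrom = "chr1"
    glo, ghi = params.gene_length_range
    gene_lengths = rng.integers(glo, ghi + 1, size=params.n_genes).tolist()
    enh_lengths = [params.tre_width] * params.n_tres
    lengths = gene_lengths + enh_lengths
    order = rng.permutation(len(lengths))
    shuffled = [lengths[i] for i in order]
    starts = _pack_intervals(rng, params.chrom_length, shuffled)
    placed = [None] * len(lengths)
    for pos, idx in zip(starts, order):
        placed[idx] = pos

    genes: list[GeneAnnotation] = []
    tres: list[dict] = []
    geometry: dict[str, tuple[int, int]] = {}
    geom_rng = child_rng(params.seed, "geometry")
    half = params.tre_width // 2
    for i in range(params.n_genes):
        start, length = placed[i], gene_lengths[i]
        strand = "+" if geom_rng.random() < 0.5 else "-"
        gene = GeneAnnotation(chrom, start, start + length, strand, f"gene{i:04d}")
        genes.append(gene)
        tre_id = f"prom{i:04d}"
        iv = Interval(chrom, max(0, gene.tss - half), gene.tss + half, tre_id)
        tres.append({"interval": iv, "class": "promoter", "active": True,
                     "gene_id": gene.id})
        sep = int(geom_rng.integers(60, 301))
        geometry[tre_id] = (sep, int(geom_rng.integers(0, 30)))
    for j in range(params.n_tres):
        start = placed[params.n_genes + j]
        tre_id = f"enh{j:04d}"
        iv = Interval(chrom, start, start + params.tre_width, tre_id)
        tres.append({"interval": iv, "class": "enhancer", "active": True})
        sep = int(geom_rng.integers(60, 301))
        geometry[tre_id] = (sep, int(geom_rng.integers(0, 30)))

    # plant fold changes on genes and enhancers; promoter TREs inherit their
    # gene's fold change (their activity is simulated from the gene)
    truth: dict[str, float] = {}
    diff_rng = child_rng(params.seed, "difftruth")
    own_ids = [g.id for g in genes] + [
        t["interval"].id for t in tres if t["class"] == "enhancer"
    ]
    n_diff = int(round(params.diff_fraction * len(own_ids)))
    chosen = diff_rng.choice(len(own_ids), size=n_diff, replace=False)
    for k, idx in enumerate(sorted(chosen)):
        sign = 1.0 if k % 2 == 0 else -1.0
        truth[own_ids[idx]] = sign * params.planted_fc
    for fid in own_ids:
        truth.setdefault(fid, 0.0)
    for t in tres:
        if t["class"] == "promoter":
            truth[t["interval"].id] = truth[t["gene_id"]]

    return ToyGenome(
        chrom_sizes={chrom: params.chrom_length},
        genes=genes,
        true_tres=tres,
        differential_truth=truth,
        pause_geometry=geometry,
    )


def _gauss_kernel(length: int, center: float, sd: float) -> np.ndarray:
    x = np.arange(length)
    return np.exp(-0.5 * ((x - center) / sd) ** 2)


def _condition_factor(log2fc: float, condition: str) -> float:
    # condition A is baseline; B applies the full planted fold change
    if condition == "A":
        return 1.0
    if condition == "B":
        return float(2.0**log2fc)
    raise ValueError(f"unknown condition label {condition!r}; expected 'A' or 'B'")


def gen_proseq_tracks(genome: ToyGenome, condition: str, params: SimParams,
                      replicate: int = 0) -> StrandTracks:
    """Simulate single-base 3'-end tracks for one condition.

    Architecture per feature class:

    * promoters — paired pause peaks on opposite strands flanking the TRE
      center (plus-strand peak downstream, minus upstream; separation drawn
      60–300 bp once per genome so both conditions share geometry), plus
      sense-strand density along the gene body;
    * enhancers — the same divergent geometry at lower intensity.

    Per-base counts are Poisson draws around the expected-rate profile;
    condition ``B`` scales differential features by their planted fold
    change.  ``pause_height``/``enhancer_height`` are apex expected reads/bp
    and ``body_density`` the per-base gene-body rate.  ``replicate`` selects
    an independent noise draw with identical expected rates.
    """
    _condition_factor(0.0, condition)  # validate label early
    rng = child_rng(params.seed, "tracks", condition, f"rep{replicate}")
    chrom, length = next(iter(genome.chrom_sizes.items()))
    rate_plus = np.zeros(length)
    rate_minus = np.zeros(length)

    for gene in genome.genes:
        fac = _condition_factor(genome.differential_truth[gene.id], condition)
        sense = rate_plus if gene.strand == "+" else rate_minus
        sense[gene.start : gene.end] += params.body_density * fac

    pause_sd = 15.0
    for tre in genome.true_tres:
        if not tre["active"]:
            continue
        iv = tre["interval"]
        tre_fc = genome.differential_truth[iv.id]
        if tre["class"] == "promoter":
            # promoter activity tracks its gene's fold change
            tre_fc = genome.differential_truth[tre["gene_id"]]
        fac = _condition_factor(tre_fc, condition)
        height = (params.pause_height if tre["class"] == "promoter"
                  else params.enhancer_height) * fac
        if height == 0:
            continue
        sep, jitter = genome.pause_geometry[iv.id]
        center = iv.center + jitter - 15
        plus_apex = center + sep // 2
        minus_apex = center - sep // 2
        lo = max(0, minus_apex - 100)
        hi = min(length, plus_apex + 100)
        rate_plus[lo:hi] += height * _gauss_kernel(hi - lo, plus_apex - lo, pause_sd)
        rate_minus[lo:hi] += height * _gauss_kernel(hi - lo, minus_apex - lo, pause_sd)

    plus = rng.poisson(rate_plus).astype(np.int64)
    minus = rng.poisson(rate_minus).astype(np.int64)
    total = int(plus.sum() + minus.sum())
    return StrandTracks(plus={chrom: plus}, minus={chrom: minus},
                        total_mapped=max(total, 1))


def gen_accessibility_truth(genome: ToyGenome, params: SimParams,
                            height: float = 10.0, sd: float = 75.0) -> dict[str, np.ndarray]:
    """Smooth accessibility-like target: one Gaussian bump per active TRE.

    Stands in for the experimental DNase-I signal the imputation model is
    trained against; zero baseline away from regulatory elements.
    """
    chrom, length = next(iter(genome.chrom_sizes.items()))
    signal = np.zeros(length)
    for tre in genome.true_tres:
        if not tre["active"]:
            continue
        c = tre["interval"].center
        lo, hi = max(0, c - 400), min(length, c + 400)
        signal[lo:hi] += height * _gauss_kernel(hi - lo, c - lo, sd)
    return {chrom: signal}


def gen_count_table(params: SimParams, n_features: int, n_per_group: int,
                    base_mean: float = 100.0, diff_fraction: float | None = None,
                    tag: str = "counts") -> tuple[pd.DataFrame, np.ndarray, pd.Series]:
    """Feature × sample NB counts for two groups with planted fold changes.

    Counts are negative binomial with dispersion ``nb_dispersion`` (variance
    mu + alpha*mu^2); a ``diff_fraction`` of features get ±``planted_fc``
    applied to group B.  Returns (counts, group labels, truth log2fc).
    """
    rng = child_rng(params.seed, tag)
    frac = params.diff_fraction if diff_fraction is None else diff_fraction
    n_diff = int(round(frac * n_features))
    truth = np.zeros(n_features)
    if n_diff:
        idx = rng.choice(n_features, size=n_diff, replace=False)
        signs = np.where(np.arange(n_diff) % 2 == 0, 1.0, -1.0)
        truth[np.sort(idx)] = signs * params.planted_fc
    base = rng.lognormal(mean=np.log(base_mean), sigma=1.0, size=n_features)
    groups = np.array(["A"] * n_per_group + ["B"] * n_per_group)
    alpha = params.nb_dispersion
    counts = np.empty((n_features, 2 * n_per_group), dtype=np.int64)
    for j, g in enumerate(groups):
        mu = base * np.where(g == "B", 2.0**truth, 1.0)
        # NB via gamma-Poisson mixture: shape 1/alpha, scale alpha*mu
        lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
        counts[:, j] = rng.poisson(lam)
    ids = [f"f{i:05d}" for i in range(n_features)]
    samples = [f"{g}{j}" for j, g in enumerate(groups)]
    df = pd.DataFrame(counts, index=ids, columns=samples)
    return df, groups, pd.Series(truth, index=ids, name="true_log2fc")


_BASES = np.array(list("ACGT"))


def gen_tre_sequences(n: int, length: int, rng: np.random.Generator,
                      gc_mean: float = 0.45, gc_sd: float = 0.08,
                      motif_consensus: str | None = None,
                      plant_fraction: float = 0.0) -> tuple[list[str], np.ndarray]:
    """Random DNA sequences with per-sequence GC content; optional planted motif.

    Returns the sequences and a boolean array marking which carry a planted
    copy of ``motif_consensus`` at a random offset.
    """
    seqs: list[str] = []
    planted = np.zeros(n, dtype=bool)
    gcs = np.clip(rng.normal(gc_mean, gc_sd, size=n), 0.2, 0.8)
    for i in range(n):
        gc = gcs[i]
        probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        seq = rng.choice(_BASES, size=length, p=probs)
        if motif_consensus and rng.random() < plant_fraction:
            off = int(rng.integers(0, length - len(motif_consensus) + 1))
            seq[off : off + len(motif_consensus)] = list(motif_consensus)
            planted[i] = True
        seqs.append("".join(seq))
    return seqs, planted


def gen_expression_cohort(params: SimParams, style: str = "tcga",
                          n_timepoints: int = 1) -> tuple[ExpressionCohort, pd.DataFrame]:
    """Samples × genes cohort with planted RET-ligand tails.

    Structure emulated:

    * four ligand genes (GDNF, NRTN, ARTN, PSPN) whose baseline expression is
      compressed below a detection-like ceiling (``scale * exp(-sigma*|z|)``)
      and whose right tail is a planted log-normal high component — a
      ``ligand_tail_fraction`` of samples belong to the tail of >= 1 ligand,
      with GDNF the most frequently affected;
    * receptor genes RET and GFRA1 correlated with an ESR1-like gene via a
      Gaussian copula targeting Spearman rho ``receptor_esr1_rho``;
    * ``style="tcga"`` — one time point, no response labels, mixed ER status;
      ``style="letrozole"`` — a small cohort with responder / nonresponder /
      NA labels and ``n_timepoints`` repeated biopsies sharing a sample mean.
      Non-responders' expected number of tail memberships is elevated by
      ``responder_shift`` (per-ligand probability + shift/4).

    Returns the cohort and a truth table (per-sample ligand tail membership).
    """
    if params.n_cohort_genes < len(LIGAND_GENES):
        raise ValueError("cohort must contain at least the 4 ligand genes")
    rng = child_rng(params.seed, "cohort", style)
    if style == "tcga":
        n = params.n_cohort_samples
        response = np.array(["NA"] * n)
    elif style == "letrozole":
        n = 52
        labels = (["responder"] * 31 + ["nonresponder"] * 13 + ["NA"] * 8)
        response = np.array(labels)
        rng.shuffle(response)
    else:
        raise ValueError(f"unknown cohort style {style!r}")

    er = np.where(rng.random(n) < params.er_positive_fraction, "ER+", "ER-")
    if style == "letrozole":
        er[:] = "ER+"  # aromatase-inhibitor cohorts are ER+

    ligands = list(LIGAND_GENES)
    membership = np.zeros((n, 4), dtype=bool)
    in_tail = rng.random(n) < params.ligand_tail_fraction
    k_probs = np.array([0.70, 0.25, 0.05])  # 1, 2 or 3 ligands per tail sample
    lig_weights = np.array([0.5, 0.2, 0.2, 0.1])  # GDNF most often high
    for i in np.flatnonzero(in_tail):
        k = 1 + rng.choice(3, p=k_probs)
        which = rng.choice(4, size=k, replace=False,
                           p=lig_weights / lig_weights.sum())
        membership[i, which] = True
    if params.responder_shift > 0:
        p_extra = min(params.responder_shift / 4.0, 0.49)
        extra = rng.random((n, 4)) < p_extra
        nonresp = response == "nonresponder"
        membership[nonresp] |= extra[nonresp]

    scale, sig0 = params.ligand_scale, params.ligand_baseline_sigma
    lig_expr = scale * np.exp(-sig0 * np.abs(rng.standard_normal((n, 4))))
    tail_vals = scale * np.exp(
        params.ligand_tail_shift + params.ligand_tail_sigma * rng.standard_normal((n, 4))
    )
    lig_expr = np.where(membership, tail_vals, lig_expr)

    # receptor block: ESR1 latent normal, RET/GFRA1 correlated via copula
    rho_s = params.receptor_esr1_rho
    rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)
    z_esr1 = rng.standard_normal(n)
    expr = {}
    for g, lig_col in zip(ligands, lig_expr.T):
        expr[g] = lig_col
    expr["ESR1"] = 50.0 * np.exp(0.5 * z_esr1)
    for g in ("RET", "GFRA1"):
        z = rho_p * z_esr1 + np.sqrt(1 - rho_p**2) * rng.standard_normal(n)
        expr[g] = 20.0 * np.exp(0.5 * z)
    for g in ("GFRA2", "GFRA3", "GFRA4"):
        expr[g] = 2.0 * np.exp(0.5 * rng.standard_normal(n))
    n_other = params.n_cohort_genes - len(expr)
    for k in range(max(n_other, 0)):
        expr[f"gene{k:03d}"] = 30.0 * np.exp(0.5 * rng.standard_normal(n))

    sample_ids = [f"s{i:04d}" for i in range(n)]
    base_expr = pd.DataFrame(expr, index=sample_ids)
    if n_timepoints <= 1:
        meta = pd.DataFrame({"sample_id": sample_ids, "response": response,
                             "er_status": er, "timepoint": 1})
        full = base_expr.reset_index(drop=True)
    else:
        rows, metas = [], []
        for t in range(1, n_timepoints + 1):
            noise = rng.lognormal(mean=0.0, sigma=0.05, size=base_expr.shape)
            rows.append(base_expr.to_numpy() * noise)
            metas.append(pd.DataFrame({"sample_id": sample_ids, "response": response,
                                       "er_status": er, "timepoint": t}))
        meta = pd.concat(metas, ignore_index=True)
        full = pd.DataFrame(np.vstack(rows), columns=base_expr.columns)

    cohort = ExpressionCohort(meta=meta, expr=full)
    truth = pd.DataFrame(membership, index=sample_ids, columns=ligands)
    truth["any_tail"] = membership.any(axis=1)
    truth["response"] = response
    truth["er_status"] = er
    return cohort, truth


def background_windows(genome: ToyGenome, n: int, width: int,
                       rng: np.random.Generator, margin: int = 500) -> list[Interval]:
    """Random windows clear of all genes and TREs (decoy candidate regions)."""
    chrom, length = next(iter(genome.chrom_sizes.items()))
    occupied = np.zeros(length, dtype=bool)
    for g in genome.genes:
        occupied[max(0, g.start - margin) : g.end + margin] = True
    for t in genome.true_tres:
        iv = t["interval"]
        occupied[max(0, iv.start - margin) : iv.end + margin] = True
    out: list[Interval] = []
    attempts = 0
    while len(out) < n and attempts < 200 * n:
        attempts += 1
        s = int(rng.integers(0, length - width))
        if not occupied[s : s + width].any():
            out.append(Interval(chrom, s, s + width, f"decoy{len(out):04d}"))
            occupied[max(0, s - margin) : s + width + margin] = True
    if len(out) < n:
        raise PackingError(f"could only place {len(out)} of {n} background windows")
    return out


def write_genome_beds(genome: ToyGenome, genes_path, tres_path) -> None:
    """Write genes and TREs as BED6 (TRE score column carries the class)."""
    with open(genes_path, "w") as fh:
        for g in genome.genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.id}\t0\t{g.strand}\n")
    with open(tres_path, "w") as fh:
        for t in genome.true_tres:
            iv = t["interval"]
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}"
                     f"\t{int(t['active'])}\t.\n")
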