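"""Synthetic functional-genomics data with known ground truth.

Every downstream stage of the dual-screen analysis is exercised against
generated inputs whose planted structure is known exactly:

* plate-structured high-content feature tables in which chosen knockdown
  "modules" share a latent phenotype (one loading vector per module,
  scaled by an effect size) on top of i.i.d. Gaussian feature noise and
  additive per-(plate, feature) batch offsets;
* negative-binomial count matrices with known per-condition log2
  fold-changes (Var = mu + dispersion * mu^2; dispersion 0 degenerates to
  Poisson), including multi-knockdown designs where module members share a
  DE signature;
* positive expression time courses with planted decay dynamics and
  multiplicative log-normal noise;
* gene annotations with peak sets enriched at promoters of chosen target
  genes, plus a matching read-coverage track.

All generators are pure functions of their parameters and a seed: a fresh
``numpy`` Generator is derived per call and no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genomics import CoverageTrack, GenomicInterval, Peak, PeakSet, promoter_windows

__all__ = [
    "ScreenTruth",
    "ExpressionTruth",
    "generate_screen",
    "generate_expression_study",
    "generate_knockdown_expression",
    "generate_time_course",
    "generate_genomic_tracks",
]


@dataclass(frozen=True)
class ScreenTruth:
    """Planted structure of a synthetic high-content screen.

    ``modules`` are disjoint sets of knockdown names sharing one latent
    loading vector each; ``effect_size`` scales that shared signal in SD
    units of the feature noise (``noise_sd``).  ``plate_shift`` is either
    the SD of random per-(plate, feature) additive offsets or an explicit
    per-plate offset map.  ``loadings`` optionally fixes the per-module
    loading vectors (length = n_features); by default they are drawn
    standard-normal from the call's RNG.
    """

    modules: tuple[frozenset[str], ...] = ()
    effect_size: float = 2.0
    noise_sd: float = 1.0
    plate_shift: float | Mapping[str, float] = 1.0
    loadings: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "modules", tuple(frozenset(m) for m in self.modules)
        )
        seen: set[str] = set()
        for m in self.modules:
            if seen & m:
                raise ValueError(f"modules are not disjoint: {sorted(seen & m)}")
            seen |= m
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")


@dataclass(frozen=True)
class ExpressionTruth:
    """Planted structure of a synthetic RNA-seq study.

    ``de_genes`` maps condition -> {gene: true log2FC vs the reference
    condition}; genes absent from a condition's map are non-DE (log2FC 0).
    ``dispersion`` is the NB dispersion alpha in Var = mu + alpha * mu^2.
    ``baseline_mu`` gives per-gene reference-condition means (drawn
    log-uniform in [100, 1000] when None); ``lib_sizes`` per-sample totals
    (drawn uniform in [0.8e6, 1.2e6] when None).
    """

    de_genes: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    dispersion: float = 0.05
    lib_sizes: Mapping[str, float] | None = None
    baseline_mu: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.lib_sizes is not None and any(
            not v > 0 for v in self.lib_sizes.values()
        ):
            raise ValueError("lib_sizes must be > 0")
        if self.baseline_mu is not None and any(
            not v > 0 for v in self.baseline_mu
        ):
            raise ValueError("baseline_mu must be > 0")


def _knockdown_names(n: int) -> list[str]:
    return [f"kd{i:03d}" for i in range(n)]


def generate_screen(
    n_knockdowns: int,
    n_features: int,
    n_replicates: int,
    n_plates: int,
    truth: ScreenTruth,
    seed: int,
) -> tuple[pd.DataFrame, ScreenTruth]:
    """Simulate a plate-structured high-content screen as a long-form table.

    Knockdowns (named ``kd000``..) are split round-robin into ``n_plates``
    layout groups; each replicate of a group is one physical plate (label
    ``plate{g}_rep{r}``), so a knockdown appears on each plate exactly
    once.  Feature values are ``effect * loading + noise + plate_offset``,
    with the shared-loading term only for module members.  Offsets are
    applied before any normalization.  Deterministic in ``seed``.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if n_knockdowns < 1 or n_plates < 1:
        raise ValueError("n_knockdowns and n_plates must be >= 1")
    knockdowns = _knockdown_names(n_knockdowns)
    known = set(knockdowns)
    for m in truth.modules:
        stray = m - known
        if stray:
            raise ValueError(
                f"module members not among knockdown names: {sorted(stray)}"
            )
    rng = np.random.default_rng(seed)
    features = [f"feat{j:02d}" for j in range(n_features)]
    if truth.loadings is not None:
        if len(truth.loadings) != len(truth.modules):
            raise ValueError("one loading vector per module is required")
        loadings = [np.asarray(l, dtype=float) for l in truth.loadings]
        if any(l.shape != (n_features,) for l in loadings):
            raise ValueError("loading vectors must have length n_features")
    else:
        loadings = [rng.standard_normal(n_features) for _ in truth.modules]
    module_of = {kd: i for i, m in enumerate(truth.modules) for kd in m}

    group = {kd: i % n_plates for i, kd in enumerate(knockdowns)}
    plates = {
        (g, r): f"plate{g}_rep{r}"
        for g in range(n_plates)
        for r in range(1, n_replicates + 1)
    }
    if isinstance(truth.plate_shift, Mapping):
        offsets = {
            p: np.full(n_features, float(truth.plate_shift.get(p, 0.0)))
            for p in plates.values()
        }
    else:
        offsets = {
            p: rng.normal(0.0, truth.plate_shift, size=n_features)
            for p in sorted(plates.values())
        }

    rows: list[tuple[str, str, int, str, float]] = []
    for kd in knockdowns:
        mi = module_of.get(kd)
        signal = truth.effect_size * loadings[mi] if mi is not None else 0.0
        for r in range(1, n_replicates + 1):
            plate = plates[(group[kd], r)]
            vals = signal + rng.normal(0.0, truth.noise_sd, size=n_features)
            vals = vals + offsets[plate]
            for f, v in zip(features, vals):
                rows.append((kd, plate, r, f, float(v)))
    table = pd.DataFrame(
        rows, columns=["knockdown", "plate", "replicate", "feature", "value"]
    )
    return table, truth


def generate_expression_study(
    n_genes: int,
    groups: Sequence[str],
    reps_per_group: int,
    truth: ExpressionTruth,
    seed: int,
) -> tuple[pd.DataFrame, ExpressionTruth]:
    """Simulate a genes x samples NB count matrix for a multi-group design.

    The first group is the reference; condition means are
    ``baseline_mu * 2**log2FC`` scaled per sample by library size relative
    to the mean library size.  Counts are Gamma-Poisson draws with
    Var = mu + dispersion * mu^2 (pure Poisson at dispersion 0).  Sample
    names are ``{group}_r{i}``.  Deterministic in ``seed``.
    """
    if reps_per_group < 2:
        raise ValueError("reps_per_group must be >= 2")
    if not groups:
        raise ValueError("at least one group is required")
    if len(set(groups)) != len(groups):
        raise ValueError("group labels must be unique")
    unknown = set(truth.de_genes) - set(groups[1:])
    if unknown:
        raise ValueError(f"de_genes conditions not in groups: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    if truth.baseline_mu is not None:
        mu0 = np.asarray(truth.baseline_mu, dtype=float)
        if mu0.shape != (n_genes,):
            raise ValueError("baseline_mu must have length n_genes")
    else:
        mu0 = np.exp(rng.uniform(np.log(100.0), np.log(1000.0), size=n_genes))
    samples = [f"{g}_r{i}" for g in groups for i in range(1, reps_per_group + 1)]
    if truth.lib_sizes is not None:
        missing = [s for s in samples if s not in truth.lib_sizes]
        if missing:
            raise ValueError(f"lib_sizes missing samples: {missing}")
        lib = np.array([truth.lib_sizes[s] for s in samples], dtype=float)
    else:
        lib = rng.uniform(0.8e6, 1.2e6, size=len(samples))
    scale = lib / lib.mean()

    lfc = np.zeros((n_genes, len(groups)))
    gene_idx = {g: i for i, g in enumerate(genes)}
    for ci, cond in enumerate(groups):
        for gene, v in truth.de_genes.get(cond, {}).items():
            if gene not in gene_idx:
                raise ValueError(f"de gene {gene!r} not among generated genes")
            lfc[gene_idx[gene], ci] = v

    counts = np.empty((n_genes, len(samples)), dtype=np.int64)
    for si, s in enumerate(samples):
        ci = si // reps_per_group
        mu = mu0 * (2.0 ** lfc[:, ci]) * scale[si]
        counts[:, si] = _nb_draw(rng, mu, truth.dispersion)
    out = pd.DataFrame(counts, index=genes, columns=samples)
    resolved = replace(
        truth,
        lib_sizes=dict(zip(samples, lib)),
        baseline_mu=tuple(mu0),
    )
    return out, resolved


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    return rng.poisson(lam)


def generate_knockdown_expression(
    knockdowns: Sequence[str],
    modules: Sequence[Iterable[str]],
    n_genes: int = 2000,
    signature_genes: int = 100,
    signature_lfc: float = 2.0,
    private_genes: int = 30,
    private_lfc: float = 2.0,
    reps_per_group: int = 3,
    dispersion: float = 0.05,
    seed: int = 0,
    control: str = "nt",
) -> tuple[pd.DataFrame, ExpressionTruth]:
    """Simulate a knockdown RNA-seq screen against a shared control.

    Members of a module share one planted DE signature (``signature_genes``
    genes at +/- ``signature_lfc``); every knockdown additionally gets its
    own private DE genes.  Returns the count matrix (control group first)
    and the resolved truth, whose ``de_genes`` maps each knockdown to its
    full gene -> log2FC map.
    """
    knockdowns = list(knockdowns)
    if control in knockdowns:
        raise ValueError("control label collides with a knockdown name")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    pool = rng.permutation(n_genes)
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        if cursor + n > n_genes:
            raise ValueError("not enough genes for the requested DE structure")
        out = [genes[i] for i in pool[cursor:cursor + n]]
        cursor += n
        return out

    module_sig: list[dict[str, float]] = []
    for _ in modules:
        sig_genes = take(signature_genes)
        signs = rng.choice([-1.0, 1.0], size=signature_genes)
        module_sig.append({g: s * signature_lfc for g, s in zip(sig_genes, signs)})
    de_genes: dict[str, dict[str, float]] = {}
    for kd in knockdowns:
        own = take(private_genes)
        signs = rng.choice([-1.0, 1.0], size=private_genes)
        table = {g: s * private_lfc for g, s in zip(own, signs)}
        for mi, m in enumerate(modules):
            if kd in set(m):
                table.update(module_sig[mi])
        de_genes[kd] = table
    truth = ExpressionTruth(de_genes=de_genes, dispersion=dispersion)
    counts, resolved = generate_expression_study(
        n_genes,
        [control] + knockdowns,
        reps_per_group,
        truth,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return counts, resolved


def generate_time_course(
    n_genes: int,
    timepoints: Sequence[str],
    decay_sets: Mapping[tuple[str, ...] | frozenset, tuple[float, float] | Sequence[float]],
    seed: int,
    baseline_log_mean: float = 3.0,
    noise_sigma: float = 0.2,
) -> pd.DataFrame:
    """Simulate a positive expression time course with planted trajectories.

    ``decay_sets`` maps gene-name collections (genes are ``g00000``..)
    to a shape: either ``(start_level, end_level)``, interpolated
    geometrically across timepoints (monotone when start > end), or an
    explicit per-timepoint level sequence.  Genes outside every set are
    flat (level 1).  Values are ``baseline * level * exp(N(0, sigma))`` —
    multiplicative noise on a strictly positive scale.
    """
    if len(timepoints) < 3:
        raise ValueError("need at least 3 timepoints")
    if len(set(timepoints)) != len(timepoints):
        raise ValueError("timepoint labels must be unique")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    known = set(genes)
    T = len(timepoints)
    levels = np.ones((n_genes, T))
    gene_idx = {g: i for i, g in enumerate(genes)}
    assigned: set[str] = set()
    for members, shape in decay_sets.items():
        members = tuple(members)
        stray = set(members) - known
        if stray:
            raise ValueError(f"set members not among generated genes: {sorted(stray)}")
        dup = set(members) & assigned
        if dup:
            raise ValueError(f"genes assigned to more than one set: {sorted(dup)}")
        assigned |= set(members)
        shape = tuple(shape)
        if len(shape) == 2 and T != 2:
            start, end = shape
            if not (start > 0 and end > 0):
                raise ValueError("shape levels must be positive")
            curve = start * (end / start) ** (np.arange(T) / (T - 1))
        elif len(shape) == T:
            if any(not v > 0 for v in shape):
                raise ValueError("shape levels must be positive")
            curve = np.asarray(shape, dtype=float)
        else:
            raise ValueError(
                f"shape must be (start, end) or one level per timepoint, got {shape}"
            )
        for g in members:
            levels[gene_idx[g]] = curve
    baseline = np.exp(rng.normal(baseline_log_mean, 0.5, size=n_genes))
    noise = np.exp(rng.normal(0.0, noise_sigma, size=(n_genes, T)))
    vals = baseline[:, None] * levels * noise
    return pd.DataFrame(vals, index=genes, columns=list(timepoints))


def generate_genomic_tracks(
    annotation_size: int,
    chrom_sizes: Mapping[str, int],
    target_genes: Iterable[str],
    frac_targeted: float,
    flank: int = 1000,
    seed: int = 0,
    n_background_peaks: int = 0,
    reads_per_peak: int = 50,
    background_read_rate: float = 1e-4,
    gene_names: Sequence[str] | None = None,
) -> tuple[list[GenomicInterval], PeakSet, CoverageTrack]:
    """Simulate a gene annotation, a summit-annotated peak set and coverage.

    Genes (``gene0000``.. unless ``gene_names`` supplies labels, e.g. to
    share a namespace with an expression study) are placed uniformly on the given chromosomes
    with random strands.  For each target gene a peak is planted with
    probability ``frac_targeted``, its summit uniform inside the
    ``+/- flank`` window around the TSS; with the complementary
    probability (and for every background peak) the peak lands uniformly
    on the genome.  Coverage consists of ``reads_per_peak`` reads piled
    normally around each summit plus uniform background reads at
    ``background_read_rate`` per bp; one read covers one bp.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    if not 0 <= frac_targeted <= 1:
        raise ValueError("frac_targeted must be in [0, 1]")
    if annotation_size < 1 or not chrom_sizes:
        raise ValueError("need at least one gene and one chromosome")
    min_size = min(chrom_sizes.values())
    if min_size < 4 * flank + 1000:
        raise ValueError("chromosomes too small for the requested flank")
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    if gene_names is None:
        gene_names = [f"gene{i:04d}" for i in range(annotation_size)]
    elif len(gene_names) != annotation_size or len(set(gene_names)) != annotation_size:
        raise ValueError("gene_names must be annotation_size unique labels")

    genes = []
    for i in range(annotation_size):
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        length = int(rng.integers(2000, 20001))
        lo = 2 * flank
        hi = chrom_sizes[chrom] - length - 2 * flank
        start = int(rng.integers(lo, max(hi, lo + 1)))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GenomicInterval(chrom, start, start + length, strand, gene_names[i])
        )
    genes.sort()
    by_name = {g.name: g for g in genes}
    target_genes = sorted(target_genes)
    stray = [t for t in target_genes if t not in by_name]
    if stray:
        raise ValueError(f"target genes not in the annotation: {stray}")

    peaks = []
    counter = 0

    def random_peak(chrom: str, summit_pos: int) -> Peak:
        nonlocal counter
        half = int(rng.integers(100, 251))
        start = max(summit_pos - half, 0)
        end = min(summit_pos + half + 1, chrom_sizes[chrom])
        p = Peak(chrom, start, end, summit_pos - start, name=f"peak{counter:04d}")
        counter += 1
        return p

    for t in target_genes:
        g = by_name[t]
        if rng.random() < frac_targeted:
            window = promoter_windows([g], upstream=flank, downstream=flank)[0]
            summit = int(rng.integers(window.start, window.end))
            peaks.append(random_peak(g.chrom, summit))
        else:
            chrom = chroms[rng.choice(len(chroms), p=probs)]
            summit = int(rng.integers(2 * flank, chrom_sizes[chrom] - 2 * flank))
            peaks.append(random_peak(chrom, summit))
    for _ in range(n_background_peaks):
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        summit = int(rng.integers(2 * flank, chrom_sizes[chrom] - 2 * flank))
        peaks.append(random_peak(chrom, summit))
    peak_set = PeakSet.build(peaks)

    positions: dict[str, list[int]] = {c: [] for c in chroms}
    for c in chroms:
        n_bg = rng.poisson(background_read_rate * chrom_sizes[c])
        positions[c].extend(rng.integers(0, chrom_sizes[c], size=n_bg).tolist())
    for p in peak_set:
        spread = max((p.end - p.start) / 4.0, 1.0)
        raw = rng.normal(p.summit_pos, spread, size=reads_per_peak)
        clipped = np.clip(np.round(raw), 0, chrom_sizes[p.chrom] - 1).astype(int)
        positions[p.chrom].extend(clipped.tolist())
    track = CoverageTrack.from_reads(positions)
    return genes, peak_set, track
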