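"""Synthetic data generation and fitness-effect simulation.

Two complementary generators:

* :func:`bernoulli_simulate` draws rare-variant indicators directly from
  the depletion model (Y ~ Bernoulli((1 - lambda_s) P)), the exact
  generative counterpart of the estimator's likelihood.
* :func:`msb_simulate` draws per-site selection coefficients from a DFE
  (point mass at zero plus a Gamma over s_het) and samples allele counts at
  mutation-selection-balance equilibrium: counts are Poisson with mean
  2 N mu / s_het. Below a strong-selection threshold the equilibrium mean
  would exceed the neutral expectation, so such sites instead draw
  rare-variant presence at the empirical neutral rate. This equilibrium
  sampler emulates a deeply sequenced panel at independent sites; it does
  not model demography (bottlenecks/growth), linkage, or sampling noise in
  the population frequency itself.

:func:`synthetic_genome` writes a deterministic FASTA-plus-tracks fixture
(neutral/target BEDs, CpG islands, per-site coverage) for end-to-end tests
of the I/O and mutation-model layers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigError, NumericalError, ValidationError
from .estimator import estimate_lambda_simple
from .io_genomics import SiteTable

#: s_het below which mutation-selection balance is not assumed and the
#: neutral rare-variant rate applies instead
STRONG_SELECTION_THRESHOLD = 1e-3


@dataclass(frozen=True)
class DFE:
    """Distribution of fitness effects over s_het.

    A mixture of a point mass at zero (weight ``pi0``) and a Gamma
    distribution with shape ``alpha`` and scale ``theta`` on the s_het
    scale. ``DFE.kim2017()`` is a published human coding-region preset
    (3.1% neutral mass, alpha = 0.1930); its Gamma scale is offered on
    both the s and s_het conventions.
    """

    pi0: float = 0.0
    alpha: float = 1.0
    theta: float = 0.01

    def __post_init__(self):
        if not 0 <= self.pi0 <= 1:
            raise NumericalError("pi0 must lie in [0, 1]")
        if self.alpha <= 0 or self.theta <= 0:
            raise NumericalError("Gamma shape and scale must be positive")

    @classmethod
    def point_mass(cls, s_het: float) -> "DFE":
        """Degenerate DFE: every site has the same s_het (tiny-variance Gamma)."""
        # shape -> inf, scale -> 0 with mean fixed; alpha = 1e6 is effectively a spike
        return cls(pi0=0.0, alpha=1e6, theta=s_het / 1e6)

    @classmethod
    def kim2017(cls, shet_scale: bool = True) -> "DFE":
        """Human coding-region DFE preset (1000 Genomes-based estimate)."""
        return cls(pi0=0.031, alpha=0.1930, theta=0.0168 if shet_scale else 0.0331)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        s = rng.gamma(shape=self.alpha, scale=self.theta, size=n)
        if self.pi0 > 0:
            s[rng.random(n) < self.pi0] = 0.0
        return s

    def bin_masses(self, edges: np.ndarray) -> np.ndarray:
        """Probability mass per histogram bin; the point mass at zero falls
        in the first bin (whose left edge must be 0)."""
        edges = np.asarray(edges, dtype=float)
        gamma = stats.gamma(a=self.alpha, scale=self.theta)
        mass = (1 - self.pi0) * np.diff(gamma.cdf(edges))
        if edges[0] == 0:
            mass[0] += self.pi0
        return mass


@dataclass
class SimResult:
    """Output of a simulation run.

    ``Y`` and ``P`` are per-draw arrays (per (site, alt) for the Bernoulli
    sampler, per site for the equilibrium sampler). ``allele_counts`` and
    ``s_het`` are filled by the equilibrium sampler; ``common`` flags sites
    whose sampled frequency reached the common cutoff (excluded from
    estimation, mirroring the estimator's site filter).
    """

    Y: np.ndarray
    P: np.ndarray
    true_lambda: float | None = None
    s_het: np.ndarray | None = None
    allele_counts: np.ndarray | None = None
    common: np.ndarray | None = None
    site_table: SiteTable | None = None
    seed: int | None = None

    def lambda_hat_simple(self) -> float:
        """Site-level closed-form estimate using the known neutral rate."""
        keep = ~self.common if self.common is not None else np.ones(len(self.Y), bool)
        n_sites = int(keep.sum())
        return estimate_lambda_simple(
            int(self.Y[keep].sum()), n_sites, float(self.P[keep].mean())
        )


def bernoulli_simulate(
    P: np.ndarray | SiteTable, lambda_s: float, seed: int
) -> SimResult:
    """Draw rare-variant indicators Y ~ Bernoulli((1 - lambda_s) P).

    ``P`` is either a flat array of per-(site, alt) probabilities or a
    SiteTable with filled P (in which case a copy with resampled Y on the
    retained rows is attached to the result).
    """
    table = None
    if isinstance(P, SiteTable):
        table = P
        parr = table.retained["P"].to_numpy(dtype=float)
        if np.isnan(parr).any():
            raise ValidationError("SiteTable P not filled")
    else:
        parr = np.asarray(P, dtype=float)
    q = (1.0 - lambda_s) * parr
    if np.any(q < 0) or np.any(q >= 1):
        raise NumericalError("(1 - lambda_s) * P must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    Y = (rng.random(len(parr)) < q).astype(np.int64)
    out_table = None
    if table is not None:
        out_table = table.copy()
        mask = ~out_table.df["excluded"]
        out_table.df.loc[mask, "Y"] = Y
        out_table.df.loc[~mask, "Y"] = 0
    return SimResult(
        Y=Y, P=parr, true_lambda=lambda_s, site_table=out_table, seed=seed
    )


def msb_simulate(
    n_sites: int,
    dfe: DFE,
    N: int = 71_702,
    mu: float = 1.2e-8,
    neutral_P: float = 0.162,
    rare_max_af: float = 0.001,
    seed: int = 0,
    strong_threshold: float = STRONG_SELECTION_THRESHOLD,
) -> SimResult:
    """Sample site-level rare-variant presence at mutation-selection balance.

    Per site: draw s_het from ``dfe``; if s_het >= ``strong_threshold``,
    draw the sampled allele count ~ Poisson(2 N mu / s_het); otherwise the
    site is in the neutral regime and draws presence ~ Bernoulli(neutral_P)
    (with count set to the indicator). A site counts as a rare variant when
    1 <= count and count / (2N) < rare_max_af; a count at or above the
    frequency cutoff flags the site common, which excludes it exactly as
    the estimator's filter would.
    """
    if N <= 0 or mu <= 0 or neutral_P <= 0:
        raise ConfigError("N, mu and neutral_P must be positive")
    if not 0 < neutral_P < 1:
        raise ConfigError("neutral_P must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    s = dfe.sample(n_sites, rng)
    strong = s >= strong_threshold
    counts = np.zeros(n_sites, dtype=np.int64)
    if strong.any():
        lam = 2.0 * N * mu / s[strong]
        counts[strong] = rng.poisson(lam)
    n_weak = int((~strong).sum())
    if n_weak:
        counts[~strong] = (rng.random(n_weak) < neutral_P).astype(np.int64)
    common_cut = max(1, int(np.floor(rare_max_af * 2 * N)))
    common = counts >= common_cut
    Y = ((counts >= 1) & ~common).astype(np.int64)
    return SimResult(
        Y=Y,
        P=np.full(n_sites, neutral_P),
        true_lambda=None,
        s_het=s,
        allele_counts=counts,
        common=common,
        seed=seed,
    )


@dataclass
class MissingDFE:
    """Histogram of s_het among the rare variants removed by selection."""

    edges: np.ndarray
    mass: np.ndarray
    clamped_mass: float


def decompose_missing_dfe(
    f: DFE,
    g_samples: np.ndarray,
    lambda_s: float,
    bins: int = 50,
    s_max: float | None = None,
) -> MissingDFE:
    """Mixture decomposition of the DFE of missing rare variants.

    If f(x) is the DFE of new mutations and g(x) the empirical DFE among
    the rare variants that survived selection, then the DFE of the variants
    selection removed is h(x) = [f(x) - (1 - lambda_s) g(x)] / lambda_s.
    Computed on a shared histogram; negative bin masses (model
    inconsistency) are clamped to zero and their total reported, then the
    histogram renormalized.
    """
    if not 0 < lambda_s <= 1:
        raise NumericalError("lambda_s must lie in (0, 1] for the decomposition")
    g_samples = np.asarray(g_samples, dtype=float)
    if s_max is None:
        upper = float(stats.gamma(a=f.alpha, scale=f.theta).ppf(0.999))
        s_max = max(upper, float(g_samples.max()) if g_samples.size else 0.0, 1e-6)
    edges = np.linspace(0.0, s_max * (1 + 1e-9), bins + 1)
    f_mass = f.bin_masses(edges)
    # tail mass beyond the last edge folded into the final bin
    f_mass[-1] += max(0.0, 1.0 - float(f_mass.sum()))
    if g_samples.size:
        g_mass, _ = np.histogram(np.clip(g_samples, 0, s_max), bins=edges)
        g_mass = g_mass / g_mass.sum()
    else:
        g_mass = np.zeros(bins)
    h = (f_mass - (1.0 - lambda_s) * g_mass) / lambda_s
    clamped = float(-h[h < 0].sum())
    h = np.clip(h, 0.0, None)
    total = h.sum()
    if total <= 0:
        raise NumericalError("decomposition produced an empty distribution")
    return MissingDFE(edges=edges, mass=h / total, clamped_mass=clamped)


# ---------------------------------------------------------------------------
# Context-structured variant generator


def context_rate_truth(
    seed: int, mean_rate: float = 0.04, log_sd: float = 0.5, max_rate: float = 0.15
) -> dict[tuple[str, str], float]:
    """A random but fixed ground-truth per-allele rare-variant rate table.

    Rates are assigned at 3-mer resolution (center base plus one flank on
    each side), log-normally dispersed around ``mean_rate``, so synthetic
    data carries genuine sequence-context signal for the mutation model to
    recover. Deterministic given ``seed``.
    """
    from itertools import product

    from .io_genomics import alt_alleles

    rng = np.random.default_rng(seed)
    truth: dict[tuple[str, str], float] = {}
    for ctx in ("".join(p) for p in product("ACGT", repeat=3)):
        for alt in alt_alleles(ctx[1]):
            rate = mean_rate * float(rng.lognormal(0.0, log_sd))
            truth[(ctx, alt)] = min(rate, max_rate)
    return truth


def true_rates_for_contexts(
    contexts: "np.ndarray | list[str]",
    alts: "np.ndarray | list[str]",
    truth: dict[tuple[str, str], float],
) -> np.ndarray:
    """Vector of ground-truth per-allele rates for aligned 7-mer context /
    alt pairs (the 3-mer core indexes the truth table)."""
    return np.array([truth[(ctx[2:5], alt)] for ctx, alt in zip(contexts, alts)])


def simulate_rare_variants(
    sequence: str,
    chrom: str,
    regions,
    truth: dict[tuple[str, str], float],
    lambda_s: float,
    seed: int,
    rare_af: float = 5e-4,
    common_fraction: float = 0.0,
    common_af: float = 0.01,
):
    """Draw VariantRecords over ``regions`` from the depletion model.

    Each (site, alt) gains a rare variant (frequency ``rare_af``) with
    probability (1 - lambda_s) times its ground-truth context rate. A
    ``common_fraction`` of sites independently gains a common variant
    (frequency ``common_af``), which the site filters will exclude.
    """
    from .io_genomics import VariantRecord, alt_alleles

    rng = np.random.default_rng(seed)
    out: list = []
    for _, start, end in regions:
        for pos in range(start, end):
            ref = sequence[pos]
            if ref not in "ACGT" or pos < 1 or pos + 2 > len(sequence):
                continue
            core = sequence[pos - 1 : pos + 2]
            if any(c not in "ACGT" for c in core):
                continue
            if common_fraction and rng.random() < common_fraction:
                alt = alt_alleles(ref)[rng.integers(3)]
                out.append(VariantRecord(chrom, pos, ref, alt, af=common_af))
                continue
            for alt in alt_alleles(ref):
                if rng.random() < (1.0 - lambda_s) * truth[(core, alt)]:
                    out.append(VariantRecord(chrom, pos, ref, alt, af=rare_af))
    return out


# ---------------------------------------------------------------------------
# Genome fixture


@dataclass
class GenomeFixture:
    """In-memory synthetic genome plus the file paths it was written to."""

    chrom: str
    sequence: str
    neutral_regions: list[tuple[str, int, int]]
    target_regions: list[tuple[str, int, int]]
    cpg_islands: list[tuple[str, int, int]]
    coverage: np.ndarray
    paths: dict = field(default_factory=dict)


def synthetic_genome(
    n_bp: int,
    seed: int,
    gc: float = 0.41,
    outdir: str | None = None,
    chrom: str = "chrS",
    target_fraction: float = 0.2,
    block: int = 5_000,
    island_fraction: float = 0.02,
    mean_coverage: float = 32.0,
    sd_coverage: float = 5.0,
) -> GenomeFixture:
    """Generate an i.i.d. random genome with covariate tracks.

    Bases are drawn independently with P(G) = P(C) = gc / 2. Alternating
    blocks are labelled neutral / target (``target_fraction`` of blocks),
    a few intervals are marked as CpG islands, and a per-site coverage
    track is drawn from a clipped normal so a small tail falls below
    typical coverage filters. Deterministic given ``seed``. When ``outdir``
    is given, writes genome.fa, neutral.bed, target.bed, cpg_islands.bed
    and coverage.tsv there.
    """
    if n_bp < 1000:
        raise ConfigError("n_bp must be >= 1000")
    if not 0 < gc < 1:
        raise NumericalError("gc must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = rng.choice(np.array(list("ACGT")), size=n_bp, p=probs)
    sequence = "".join(bases)

    # alternating neutral/target blocks, flanks trimmed for 7-mer contexts
    neutral, target = [], []
    n_blocks = max(1, n_bp // block)
    period = max(1, round(1 / target_fraction)) if target_fraction > 0 else 0
    for b in range(n_blocks):
        start = b * block
        end = min((b + 1) * block, n_bp)
        start = max(start, 3)
        end = min(end, n_bp - 3)
        if start >= end:
            continue
        if period and (b % period == period - 1):
            target.append((chrom, start, end))
        else:
            neutral.append((chrom, start, end))

    # CpG islands: scattered 500 bp intervals
    islands = []
    n_islands = max(1, int(island_fraction * n_bp / 500))
    for start in sorted(rng.choice(max(1, n_bp - 500), size=n_islands, replace=False)):
        islands.append((chrom, int(start), int(start) + 500))

    coverage = np.clip(rng.normal(mean_coverage, sd_coverage, size=n_bp), 1.0, None)

    fixture = GenomeFixture(
        chrom=chrom,
        sequence=sequence,
        neutral_regions=neutral,
        target_regions=target,
        cpg_islands=islands,
        coverage=coverage,
    )
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "fasta": os.path.join(outdir, "genome.fa"),
            "neutral": os.path.join(outdir, "neutral.bed"),
            "target": os.path.join(outdir, "target.bed"),
            "cpg": os.path.join(outdir, "cpg_islands.bed"),
            "coverage": os.path.join(outdir, "coverage.tsv"),
        }
        with open(paths["fasta"], "w") as fh:
            fh.write(f">{chrom}\n")
            for i in range(0, n_bp, 60):
                fh.write(sequence[i : i + 60] + "\n")
        for key, regions in (
            ("neutral", neutral),
            ("target", target),
            ("cpg", islands),
        ):
            with open(paths[key], "w") as fh:
                for c, s, e in regions:
                    fh.write(f"{c}\t{s}\t{e}\n")
        with open(paths["coverage"], "w") as fh:
            fh.write("chrom\tpos0\tcoverage\n")
            for i, cov in enumerate(coverage):
                fh.write(f"{chrom}\t{i}\t{cov:.3f}\n")
        fixture.paths = paths
    return fixture
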