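"""Synthetic pooled-sequencing data with known truth.

Every downstream stage of the package is exercised against data generated
here: diverged strain panels with strain-private substitutions, pooled
samples with skewed mixture proportions and Poisson (optionally negative
binomial) coverage, planted duplications and cross-strain fragments, and
haplotype windows that supply exact brute-force oracles for the
population-genetic estimators.

Reads are simulated at the summary level the pipeline actually consumes —
per-position depth tracks and per-site allele counts — not as FASTQ;
external mappers are out of scope. All generators are pure functions of
their arguments and a seed, with per-sample substreams spawned from the
global seed via :class:`numpy.random.SeedSequence` so each sample is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import ReferencePanel, find_diagnostic_sites

__all__ = [
    "SimulationTruth",
    "PooledSample",
    "simulate_strain_panel",
    "simulate_pooled_sample",
    "simulate_coverage_bias",
    "simulate_haplotype_window",
    "pooled_counts_from_haplotypes",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class TruthError(ValueError):
    """Truth object inconsistent with the panel it is applied to."""


@dataclass
class SimulationTruth:
    """Ground truth of one simulated pooled population.

    ``planted_cnv`` rows are ``(contig, start, end, copy_number,
    carrier_frequency)`` with half-open coordinates; ``planted_hgt`` rows
    are ``(donor_strain, contig, start, end, frequency)``.
    """

    strain_mixture: np.ndarray
    planted_cnv: list[tuple[str, int, int, float, float]] = field(default_factory=list)
    planted_hgt: list[tuple[str, str, int, int, float]] = field(default_factory=list)
    error_rate: float = 0.0
    seed: int = 0
    private_sites: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.strain_mixture, dtype=float)
        if np.any((m < 0) | (m > 1)):
            raise ValueError("mixture proportions must lie in [0, 1]")
        if abs(m.sum() - 1.0) > 1e-12:
            raise ValueError(f"mixture proportions sum to {m.sum()}, not 1")
        for *_, start, end, _cn, _f in [(None, *c) for c in self.planted_cnv]:
            if not start < end:
                raise ValueError("CNV intervals must satisfy start < end")
        for _donor, _contig, start, end, freq in self.planted_hgt:
            if not start < end:
                raise ValueError("HGT intervals must satisfy start < end")
            if not 0 <= freq <= 1:
                raise ValueError("HGT frequency must lie in [0, 1]")
        for *_rest, cf in self.planted_cnv:
            if not 0 <= cf <= 1:
                raise ValueError("carrier frequency must lie in [0, 1]")
        self.strain_mixture = m

    def with_mixture(self, mixture) -> "SimulationTruth":
        return replace(self, strain_mixture=np.asarray(mixture, dtype=float))


@dataclass
class PooledSample:
    """One simulated pooled population sample.

    ``depth`` maps contig to the per-position focal/metareference depth
    track; ``pileup`` holds base counts at the panel's diagnostic sites
    (columns ``contig, position, depth, A, C, G, T``); ``nonfocal_depth``
    maps donor strain to per-contig depth tracks of reads uniquely best
    assigned to that donor.
    """

    sample_id: str
    depth: dict[str, np.ndarray]
    pileup: pd.DataFrame
    nonfocal_depth: dict[str, dict[str, np.ndarray]]
    mean_coverage: float
    seed: int


def _contig_spans(genome_length: int, n_contigs: int) -> list[tuple[int, int]]:
    bounds = np.linspace(0, genome_length, n_contigs + 1).astype(int)
    return [(int(a), int(b)) for a, b in zip(bounds, bounds[1:])]


def simulate_strain_panel(
    n_strains: int = 5,
    genome_length: int = 50_000,
    n_contigs: int = 2,
    divergence: float = 0.01,
    seed: int = 0,
    n_plasmid_contigs: int = 0,
    strain_ids: list[str] | None = None,
) -> tuple[ReferencePanel, SimulationTruth]:
    """Simulate an aligned panel of diverged strain genomes.

    Starting from a random ancestral sequence, each strain independently
    substitutes each site with probability ``divergence`` (to a uniformly
    chosen different base), so strain-private diagnostic sites arise at
    rate ``divergence * (1 - divergence)**(n_strains - 1)`` per strain.
    The returned truth records every strain-private site and carries a
    uniform mixture; callers set the mixture of interest with
    :meth:`SimulationTruth.with_mixture`.
    """
    if n_strains < 2:
        raise ValueError("need at least 2 strains")
    if genome_length < n_contigs or genome_length <= 0:
        raise ValueError("genome_length must be positive and >= n_contigs")
    if not 0 <= divergence <= 0.2:
        raise ValueError("divergence must lie in [0, 0.2]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ancestral = _BASES[rng.integers(0, 4, size=genome_length)]
    seqs = []
    for _ in range(n_strains):
        s = ancestral.copy()
        mask = rng.random(genome_length) < divergence
        n_mut = int(mask.sum())
        # substitute to one of the 3 other bases, uniformly
        shift = rng.integers(1, 4, size=n_mut)
        idx = (np.searchsorted(_BASES, s[mask]) + shift) % 4
        s[mask] = _BASES[idx]
        seqs.append(s.tobytes().decode())
    if strain_ids is None:
        strain_ids = [f"S{i + 1}" for i in range(n_strains)]
    spans = _contig_spans(genome_length, n_contigs)
    roles = ["chromosomal"] * n_contigs
    for i in range(n_plasmid_contigs):
        roles[n_contigs - 1 - i] = "plasmid"
    contig_table = pd.DataFrame(
        {
            "contig": [f"contig{i + 1}" for i in range(n_contigs)],
            "start": [a for a, _ in spans],
            "end": [b for _, b in spans],
            "role": roles,
        }
    )
    panel = ReferencePanel(
        strain_ids=strain_ids,
        aligned_sequences=seqs,
        contig_table=contig_table,
        focal_strain=strain_ids[0],
    )
    truth = SimulationTruth(
        strain_mixture=np.full(n_strains, 1.0 / n_strains),
        seed=seed,
        private_sites=find_diagnostic_sites(panel),
    )
    return panel, truth


def _cnv_factor(
    truth: SimulationTruth, contig: str, length: int, offset: int
) -> np.ndarray:
    """Multiplicative coverage factor 1 + f*(cn - 1) over one contig."""
    factor = np.ones(length)
    for c, start, end, cn, cf in truth.planted_cnv:
        if c != contig:
            continue
        lo, hi = max(0, start - offset), min(length, end - offset)
        if lo < hi:
            factor[lo:hi] *= 1.0 + cf * (cn - 1.0)
    return factor


def simulate_coverage_bias(
    contig_lengths: dict[str, int], cv: float = 0.15, seed: int = 0
) -> dict[str, np.ndarray]:
    """Per-position coverage multipliers shared across samples.

    Real pooled libraries share a systematic positional coverage profile
    (GC content, mappability, library chemistry), so the depth at a given
    position is correlated across samples even though samples are
    independent pools. This helper draws a lognormal multiplier with unit
    mean and coefficient of variation ``cv`` (default 0.15, a typical
    magnitude for bacterial Illumina coverage bias) independently per
    position; pass the result as ``bias`` to
    :func:`simulate_pooled_sample` for every sample of a cohort. The
    shared profile is what gives the rank-variance CNV detector its
    power: it pins each null position's rank to a consistent value across
    samples, while positions where only some populations carry a CNV
    break rank. With ``bias=None`` coverage is exchangeable across
    positions and rank variance carries almost no per-position CNV
    signal.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sigma2 = np.log(1.0 + cv**2)
    return {
        c: rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=n)
        for c, n in contig_lengths.items()
    }


def simulate_pooled_sample(
    panel: ReferencePanel,
    truth: SimulationTruth,
    mean_coverage: float = 100.0,
    sample_id: str = "sample1",
    seed: int | None = None,
    dispersion: float | None = None,
    bias: dict[str, np.ndarray] | None = None,
) -> PooledSample:
    """Simulate depth tracks and diagnostic-site allele counts for one pool.

    Per-position depth is Poisson(``mean_coverage``) multiplied inside each
    planted CNV by ``1 + carrier_frequency * (copy_number - 1)``; setting
    ``dispersion`` switches to a negative binomial with that size
    parameter (overdispersion hook, off by default). At each diagnostic
    site the base counts are multinomial over A/C/G/T: a read shows the
    diagnostic allele with probability ``p(1-e) + (1-p)e/3`` where ``p``
    is the diagnostic strain's mixture proportion and ``e`` the symmetric
    per-base error rate. Planted HGT fragments contribute donor-assigned
    depth at ``mean_coverage * frequency`` on donor coordinates. A
    ``bias`` profile from :func:`simulate_coverage_bias` multiplies the
    Poisson rate position-wise to emulate the systematic coverage
    structure shared across real libraries (default off, so the marginal
    depth distribution is exactly Poisson).
    """
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    if len(truth.strain_mixture) != panel.n_strains:
        raise TruthError("mixture length does not match panel strains")
    contigs = set(panel.contig_table["contig"])
    for c, *_ in truth.planted_cnv:
        if c not in contigs:
            raise TruthError(f"planted CNV references unknown contig {c!r}")
    for donor, c, *_ in truth.planted_hgt:
        if donor not in panel.strain_ids:
            raise TruthError(f"planted HGT references unknown strain {donor!r}")
        if c not in contigs:
            raise TruthError(f"planted HGT references unknown contig {c!r}")
    if seed is None:
        seed = truth.seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    depth: dict[str, np.ndarray] = {}
    for _, row in panel.contig_table.iterrows():
        contig, start, end = row["contig"], int(row["start"]), int(row["end"])
        lam = mean_coverage * _cnv_factor(truth, contig, end - start, 0)
        if bias is not None:
            lam = lam * bias[contig]
        if dispersion is None:
            depth[contig] = rng.poisson(lam)
        else:
            # NB with mean lam and size r: var = lam + lam^2/r
            r = dispersion
            depth[contig] = rng.negative_binomial(r, r / (r + lam))

    sites = truth.private_sites
    if sites is None:
        sites = find_diagnostic_sites(panel)
    e = truth.error_rate
    mix = {s: float(p) for s, p in zip(panel.strain_ids, truth.strain_mixture)}
    records = []
    base_order = ["A", "C", "G", "T"]
    for _, row in sites.iterrows():
        d = int(depth[row["contig"]][row["position"]])
        p = mix[row["diagnostic_strain"]]
        p_diag = p * (1 - e) + (1 - p) * e / 3
        others = [b for b in base_order if b not in (row["diagnostic_allele"], row["background_allele"])]
        probs = {b: e / 3 for b in others}
        probs[row["diagnostic_allele"]] = p_diag
        probs[row["background_allele"]] = 1.0 - p_diag - 2 * e / 3
        counts = rng.multinomial(d, [probs[b] for b in base_order]) if d > 0 else np.zeros(4, int)
        records.append(
            {
                "contig": row["contig"],
                "position": int(row["position"]),
                "depth": d,
                **{b: int(c) for b, c in zip(base_order, counts)},
            }
        )
    pileup = pd.DataFrame(
        records, columns=["contig", "position", "depth", *base_order]
    )

    nonfocal: dict[str, dict[str, np.ndarray]] = {}
    lengths = {
        row["contig"]: int(row["end"]) - int(row["start"])
        for _, row in panel.contig_table.iterrows()
    }
    for donor, contig, start, end, freq in truth.planted_hgt:
        tracks = nonfocal.setdefault(donor, {})
        track = tracks.setdefault(contig, np.zeros(lengths[contig], dtype=int))
        lo, hi = max(0, start), min(lengths[contig], end)
        if freq > 0 and lo < hi:
            track[lo:hi] += rng.poisson(mean_coverage * freq, size=hi - lo)

    return PooledSample(
        sample_id=sample_id,
        depth=depth,
        pileup=pileup,
        nonfocal_depth=nonfocal,
        mean_coverage=mean_coverage,
        seed=seed,
    )


def simulate_haplotype_window(
    n_haplotypes: int,
    length: int,
    theta_per_site: float,
    seed: int = 0,
) -> np.ndarray:
    """Simulate an infinite-sites haplotype window under the neutral SFS.

    Mutations are placed site by site: each site is segregating with
    probability ``theta_per_site * a1(n)`` (so ``E[S] = theta * L * a1``,
    the Watterson expectation), and a segregating site's derived-allele
    count ``i`` is drawn from the neutral site-frequency spectrum
    ``P(i) ∝ 1/i`` and assigned to a uniformly chosen subset of
    haplotypes. This per-site placement reproduces the neutral
    expectations ``E[theta_W] = E[pi] = theta`` without simulating a
    genealogy; linkage between sites is absent, so the variance of window
    statistics is smaller than the coalescent's.

    Returns the 0/1 haplotype matrix of shape ``(n_haplotypes, length)``.
    """
    if n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    if length <= 0:
        raise ValueError("length must be positive")
    if theta_per_site < 0:
        raise ValueError("theta_per_site must be non-negative")
    n = n_haplotypes
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    H = np.zeros((n, length), dtype=np.int8)
    if theta_per_site == 0:
        return H
    a1 = np.sum(1.0 / np.arange(1, n))
    p_seg = min(1.0, theta_per_site * a1)
    seg = np.nonzero(rng.random(length) < p_seg)[0]
    sfs = 1.0 / np.arange(1, n)
    sfs /= sfs.sum()
    counts = rng.choice(np.arange(1, n), size=seg.size, p=sfs)
    for pos, i in zip(seg, counts):
        carriers = rng.choice(n, size=i, replace=False)
        H[carriers, pos] = 1
    return H


def pooled_counts_from_haplotypes(
    haplotypes: np.ndarray,
    coverage: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Derive pooled per-site counts from an explicit haplotype matrix.

    With ``coverage=None`` the pool is read noise-free: each segregating
    site is reported at depth ``n`` (the number of haplotypes) with the
    exact derived count, so pooled estimators can be compared exactly with
    haplotype-matrix oracles. With a numeric ``coverage``, depth is
    Poisson and the derived count binomial at the true frequency.

    Returns a DataFrame with columns ``contig, position, coverage, freq``
    covering the segregating sites.
    """
    H = np.asarray(haplotypes)
    n, L = H.shape
    derived = H.sum(axis=0)
    seg = np.nonzero((derived > 0) & (derived < n))[0]
    if coverage is None:
        depth = np.full(seg.size, n, dtype=int)
        alt = derived[seg]
    else:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        depth = rng.poisson(coverage, size=seg.size)
        depth = np.maximum(depth, 2)
        alt = rng.binomial(depth, derived[seg] / n)
    with np.errstate(invalid="ignore"):
        freq = np.where(depth > 0, alt / depth, 0.0)
    return pd.DataFrame(
        {
            "contig": "window",
            "position": seg,
            "coverage": depth,
            "freq": freq,
        }
    )
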