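"""Synthetic study generator.

Emulates the statistical structure of MNase-protection nucleosome maps
around transcription-factor binding sites in a compact random genome:

* per-bp tag-count tracks are Poisson draws around a mean depth;
* in vivo chromatin shows a nucleosome-depleted region (NDR) at bound
  sites, with the displaced mass piled into phased flanking nucleosomes;
* intrinsic (in vitro reconstituted) chromatin follows one of several
  regimes -- a narrow NDR, a broad promoter-scale depression with the
  site-local fine structure randomized, a site occluded by a well-bound
  nucleosome inside a poor region, or enriched flanks;
* crosslinked chromatin equals the in vivo map plus excess tags over a
  nucleosome-sized span at "labile" bound sites;
* a matching qPCR Ct table encodes ChIP enrichment anti-correlated with
  occupancy.

Bound-site heterogeneity matters: ChIP-based "bound" calls include sites
with little or no depletion, which is why real depletion-vs-binding AUCs
sit in the 0.6-0.8 range rather than near 1.  The generator reproduces
this by leaving a fraction of bound sites without any planted NDR and
drawing the remaining dip depths uniformly up to a maximum.

All randomness flows from one explicit seed; identical config + seed give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError
from .genome import BASES, GenomeSequence, PwmRecord, reverse_complement
from .sites import PROMOTER_LENGTH, PVALUE_BIN_EDGES
from .tagmap import TAG_LENGTH, TagMap

REGIMES = (
    "local_ndr",
    "regional_depletion",
    "occluded_site",
    "flank_enriched",
    "broad_poor",
)

#: half the nucleosome footprint; the first phased nucleosome sits this far
#: beyond the NDR edge
_HALF_NUC = 73


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults describe a compact but realistic promoter landscape: a 300-kb
    chromosome with 300 evenly spaced genes (600-bp promoters, so bound
    promoters are a sixth of the random-promoter background rather than
    dominating it), 50 bound and 60 unbound planted motifs, 10x mean tag
    depth, NDRs up to 80% deep with half of nominally bound sites lacking
    one (ChIP-based "bound" calls are liberal, which is why real
    depletion-vs-binding AUCs sit around 0.6-0.8), 165-bp phased flanking
    nucleosomes, an in vitro positioning signal of amplitude 0.6 (a
    few-fold peak-to-trough occupancy ratio), half the bound sites labile
    with +5 tags/bp of crosslink excess -- lability is assigned
    preferentially to NDR-bearing sites, since TF competition produces
    both -- and qPCR enrichment of ~8-fold at an average bound site
    falling 2-fold per occupancy SD with 0.5-cycle noise.
    """

    n_chromosomes: int = 1
    chromosome_length: int = 300_000
    n_genes: int = 300
    motif_length: int = 8
    n_bound_sites: int = 50
    n_unbound_motifs: int = 60
    regime: str = "local_ndr"
    mean_depth: float = 10.0
    depletion_depth: float = 0.8        # max fractional dip (0 = none)
    frac_no_ndr: float = 0.5            # bound sites with no planted NDR
    depletion_width: float = 150.0      # NDR full width at half depth, bp
    phasing_amplitude: float = 0.4
    nucleosome_repeat: float = 165.0
    fine_structure_amplitude: float = 0.6  # genome-wide positioning signal
    labile_fraction: float = 0.5
    labile_excess: float = 5.0          # extra tags/bp at labile sites
    qpcr_slope: float = 1.0             # -d(log2 enrichment)/d(occupancy SD)
    qpcr_noise_sd: float = 0.5
    qpcr_baseline_log2: float = 3.0     # mean log2 enrichment of bound sites
    qpcr_replicates: int = 3
    tf_name: str = "TF1"

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ConfigError(f"unknown regime {self.regime!r}")
        for name in ("n_chromosomes", "chromosome_length", "n_genes",
                     "motif_length", "n_bound_sites", "n_unbound_motifs",
                     "qpcr_replicates"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.depletion_depth <= 1.0:
            raise ConfigError("depletion_depth must be in [0, 1]")
        if not 0.0 <= self.labile_fraction <= 1.0:
            raise ConfigError("labile_fraction must be in [0, 1]")
        if not 0.0 <= self.frac_no_ndr <= 1.0:
            raise ConfigError("frac_no_ndr must be in [0, 1]")
        if self.qpcr_slope < 0:
            raise ConfigError(
                "qpcr_slope must be >= 0 (anti-correlation is encoded by "
                "the minus sign in the enrichment model)"
            )


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)


def generate_genome(cfg: SimConfig, seed) -> tuple[GenomeSequence, pd.DataFrame]:
    """Random uniform-ACGT genome plus evenly spaced gene starts.

    Gene starts are spaced so the 600-bp promoters upstream of them never
    overlap; a small deterministic jitter keeps the layout from being
    perfectly periodic.
    """
    rng = _as_rng(seed)
    base = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequences = {}
    gene_rows = []
    genes_left = cfg.n_genes
    per_chrom = -(-cfg.n_genes // max(cfg.n_chromosomes, 1))
    for i in range(cfg.n_chromosomes):
        name = f"chr{i + 1}"
        codes = rng.integers(0, 4, size=cfg.chromosome_length)
        sequences[name] = base[codes].tobytes().decode("ascii")
        n_here = min(per_chrom, genes_left)
        genes_left -= n_here
        if n_here:
            spacing = cfg.chromosome_length // (n_here + 1)
            if spacing < PROMOTER_LENGTH + 20:
                raise ConfigError(
                    "chromosome too short for non-overlapping promoters"
                )
            jitter_max = min(100, (spacing - PROMOTER_LENGTH - 20) // 2)
            jitter = rng.integers(-jitter_max, jitter_max + 1, size=n_here) \
                if jitter_max > 0 else np.zeros(n_here, dtype=int)
            starts = (np.arange(1, n_here + 1) * spacing + jitter)
            for gs in starts:
                gene_rows.append({"chrom": name, "gene_start": int(gs)})
    genome = GenomeSequence(sequences)
    gene_starts = pd.DataFrame(gene_rows, columns=["chrom", "gene_start"])
    return genome, gene_starts


def random_pwm(length: int, seed, consensus_prob: float = 0.85,
               name: str = "TF1") -> PwmRecord:
    """Near-deterministic PWM with a random consensus sequence."""
    rng = _as_rng(seed)
    cons = rng.integers(0, 4, size=length)
    mat = np.full((length, 4), (1.0 - consensus_prob) / 3.0)
    mat[np.arange(length), cons] = consensus_prob
    return PwmRecord(tf_name=name, matrix=mat)


def plant_sites(
    genome: GenomeSequence,
    gene_starts: pd.DataFrame,
    pwm: PwmRecord,
    cfg: SimConfig,
    seed,
) -> tuple[GenomeSequence, pd.DataFrame]:
    """Write PWM consensus sequences into distinct promoters.

    Bound sites receive chip_p drawn log-uniformly below 1e-3; unbound
    motifs get chip_p spread evenly across the four standard bins
    (1e-3,1e-2], (1e-2,1e-1], (1e-1,0.5], (0.5,1], uniform within a bin.

    Returns the edited genome and a site table with ground-truth columns
    (site_id, bound, dip depth, labile flag).
    """
    rng = _as_rng(seed)
    m = len(pwm)
    if m > PROMOTER_LENGTH:
        raise ConfigError("motif longer than promoter")
    n_sites = cfg.n_bound_sites + cfg.n_unbound_motifs
    if n_sites > len(gene_starts):
        raise ConfigError("more sites than promoters")
    chosen = rng.choice(len(gene_starts), size=n_sites, replace=False)
    consensus = pwm.consensus

    seqs = {name: bytearray(genome[name], "ascii") for name in genome.names}
    rows = []
    for k, gi in enumerate(chosen):
        g = gene_starts.iloc[gi]
        prom_start = max(int(g["gene_start"]) - PROMOTER_LENGTH, 0)
        margin = 150
        lo = prom_start + margin
        hi = int(g["gene_start"]) - margin - m
        if hi <= lo:  # short promoter at a chromosome edge
            lo, hi = prom_start, int(g["gene_start"]) - m
        start = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        written = consensus if strand == "+" else reverse_complement(consensus)
        seqs[g["chrom"]][start : start + m] = written.encode("ascii")
        bound = k < cfg.n_bound_sites
        if bound:
            chip_p = 10.0 ** rng.uniform(-6.0, -3.0)
            no_ndr = rng.random() < cfg.frac_no_ndr
            dip = 0.0 if no_ndr else float(
                rng.uniform(0.0, cfg.depletion_depth))
            labile = False  # assigned below, preferentially at NDR sites
        else:
            bin_i = int(rng.integers(0, 4))
            lo_p, hi_p = PVALUE_BIN_EDGES[bin_i], PVALUE_BIN_EDGES[bin_i + 1]
            chip_p = float(rng.uniform(lo_p, hi_p))
            dip, labile = 0.0, False
        rows.append(
            {
                "site_id": f"site_{k:04d}",
                "tf": cfg.tf_name,
                "chrom": g["chrom"],
                "start": start,
                "end": start + m,
                "strand": strand,
                "chip_p": chip_p,
                "bound": bound,
                "regime": cfg.regime,
                "dip_depth": dip,
                "labile": labile,
            }
        )
    edited = GenomeSequence(
        {name: bs.decode("ascii") for name, bs in seqs.items()}
    )
    table = pd.DataFrame(rows)
    # labile (crosslink-trapped) nucleosomes arise from TF-nucleosome
    # competition, so assign lability preferentially to NDR-bearing bound
    # sites; spill over to the rest only if there are not enough
    n_labile = int(round(cfg.labile_fraction * cfg.n_bound_sites))
    if n_labile:
        bound_idx = np.flatnonzero(table["bound"].to_numpy())
        order = rng.permutation(bound_idx)
        dipped = [i for i in order if table.at[i, "dip_depth"] > 0]
        undipped = [i for i in order if table.at[i, "dip_depth"] == 0]
        pick = (dipped + undipped)[:n_labile]
        table.loc[pick, "labile"] = True
    return edited, table


def _gauss(d: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * (d / sigma) ** 2)


def _invivo_site_factor(d: np.ndarray, dip: float, cfg: SimConfig) -> np.ndarray:
    """Multiplicative occupancy factor around one bound site in vivo.

    A Gaussian NDR of full width ``depletion_width`` at half depth, with
    the displaced mass compensated by bumps at the first flanking
    nucleosome positions (mass-conserving over a promoter-scale window,
    which is what makes broad averages of in vivo data uninformative), plus
    a decaying cosine phasing term.
    """
    sigma = cfg.depletion_width / 2.355
    c0 = cfg.depletion_width / 2.0 + _HALF_NUC
    sigma_c = 60.0
    ad = np.abs(d)
    dipterm = dip * _gauss(d, sigma)
    comp = dip * (sigma / (2.0 * sigma_c)) * _gauss(ad - c0, sigma_c)
    factor = 1.0 - dipterm + comp
    outside = ad > cfg.depletion_width / 2.0
    osc = (
        cfg.phasing_amplitude
        * np.cos(2.0 * np.pi * (ad - c0) / cfg.nucleosome_repeat)
        * np.exp(-np.maximum(ad - c0, 0.0) / (1.5 * cfg.nucleosome_repeat))
    )
    factor = factor + np.where(outside, dip * osc, 0.0)
    return np.maximum(factor, 0.0)


def _invitro_site_factor(d: np.ndarray, dip: float, cfg: SimConfig,
                         region_offset: float = 0.0) -> np.ndarray:
    """Multiplicative occupancy factor around one bound site in vitro,
    by regime (applied on top of the genome-wide positioning signal).

    ``region_offset`` displaces the broad depression relative to the site:
    in the broad regimes the site lies somewhere inside a poor region, not
    at its minimum, so the site-local value carries no information beyond
    the regional level.
    """
    regime = cfg.regime
    if regime == "local_ndr":
        return _invivo_site_factor(d, dip, cfg)
    if regime in ("broad_poor", "regional_depletion"):
        # promoter-scale smooth depression; no deterministic structure at
        # the site itself (its fine structure comes from the random-phase
        # positioning signal and the random placement within the region)
        return np.maximum(1.0 - dip * _gauss(d - region_offset, 300.0), 0.0)
    if regime == "occluded_site":
        # poor region, but a well-bound nucleosome sits on the site
        broad = 1.0 - dip * _gauss(d - region_offset, 300.0)
        bump = 1.0 + 0.8 * _gauss(d, 30.0)
        return np.maximum(broad * bump, 0.0)
    if regime == "flank_enriched":
        # narrow NDR with over-compensated, strongly occupied flanks
        sigma = cfg.depletion_width / 2.355
        c0 = cfg.depletion_width / 2.0 + _HALF_NUC
        factor = (1.0 - dip * _gauss(d, sigma)
                  + 2.0 * dip * _gauss(np.abs(d) - c0, 60.0))
        return np.maximum(factor, 0.0)
    raise ConfigError(f"unknown regime {regime!r}")


def simulate_tag_maps(
    genome: GenomeSequence,
    site_table: pd.DataFrame,
    cfg: SimConfig,
    seed,
) -> tuple[dict[str, TagMap], dict[str, dict[str, np.ndarray]]]:
    """Poisson tag-count tracks for the in vivo, in vitro, and crosslinked
    libraries.

    Returns ``(maps, rates)`` where ``maps`` has keys ``invivo``,
    ``invitro``, ``xlink`` and ``rates`` holds the underlying per-bp Poisson
    rates (used e.g. to sample explicit tag starts).
    """
    rng = _as_rng(seed)
    span = 900  # bp of planted structure on either side of a site
    rates: dict[str, dict[str, np.ndarray]] = {
        "invivo": {}, "invitro": {}, "xlink": {}}
    for name, length in genome.lengths.items():
        base = np.full(length, cfg.mean_depth)
        vivo = base.copy()
        # genome-wide nucleosome positioning signal, independent phases
        x = np.arange(length)
        amp = cfg.fine_structure_amplitude
        vitro = base * (
            1.0 + amp * np.cos(
                2.0 * np.pi * x / cfg.nucleosome_repeat
                + rng.uniform(0.0, 2.0 * np.pi))
        )
        here = site_table[(site_table["chrom"] == name) & site_table["bound"]]
        for row in here.itertuples(index=False):
            c = (row.start + row.end - 1) // 2
            lo, hi = max(c - span, 0), min(c + span + 1, length)
            d = np.arange(lo, hi) - c
            offset = float(rng.uniform(-250.0, 250.0))
            vivo[lo:hi] *= _invivo_site_factor(d, row.dip_depth, cfg)
            vitro[lo:hi] *= _invitro_site_factor(d, row.dip_depth, cfg,
                                                 region_offset=offset)
        xlink = vivo.copy()
        labile = here[here["labile"]]
        for row in labile.itertuples(index=False):
            c = (row.start + row.end - 1) // 2
            lo, hi = max(c - _HALF_NUC, 0), min(c + _HALF_NUC, length)
            xlink[lo:hi] += cfg.labile_excess
        rates["invivo"][name] = vivo
        rates["invitro"][name] = np.maximum(vitro, 0.0)
        rates["xlink"][name] = xlink
    maps = {
        key: TagMap({name: rng.poisson(rate).astype(float)
                     for name, rate in per_chrom.items()})
        for key, per_chrom in rates.items()
    }
    return maps, rates


def sample_tag_starts(
    rate: dict[str, np.ndarray], seed, tag_length: int = TAG_LENGTH
) -> pd.DataFrame:
    """Draw explicit 146-bp tag 5' starts whose pileup approximates the
    given per-bp rate track.  Returns columns (chrom, start)."""
    rng = _as_rng(seed)
    rows = []
    for chrom, r in rate.items():
        r = np.maximum(np.asarray(r, dtype=float), 0.0)
        usable = r[: max(r.size - tag_length + 1, 1)].copy()
        total = usable.sum()
        if total <= 0:
            continue
        n_tags = int(rng.poisson(total / tag_length))
        starts = rng.choice(usable.size, size=n_tags, p=usable / total)
        rows.append(pd.DataFrame({"chrom": chrom, "start": np.sort(starts)}))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start"])
    return pd.concat(rows, ignore_index=True)


def simulate_qpcr(
    site_table: pd.DataFrame,
    occupancy_sd_units: np.ndarray,
    cfg: SimConfig,
    seed,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct table encoding ChIP enrichment anti-correlated with occupancy.

    Per assayed site the planted log2 enrichment is
    ``baseline - slope * occupancy_SD + noise``; the baseline reflects that
    assayed sites are genuinely bound (~8-fold enriched on average by
    default), so the clamp at fold 1 rarely bites.  The value is converted
    to Ct rows (fixed ct_input; ct_ip lowered by the enrichment) with two
    noise-free control sites per replicate at enrichment 1.

    Returns ``(ct_table, truth)`` where truth carries the planted log2
    enrichment per site.
    """
    rng = _as_rng(seed)
    occ = np.asarray(occupancy_sd_units, dtype=float)
    if len(site_table) != occ.size:
        raise ConfigError("occupancy vector does not match site table")
    log2e = (
        cfg.qpcr_baseline_log2
        - cfg.qpcr_slope * occ
        + rng.normal(0.0, cfg.qpcr_noise_sd, size=occ.size)
    )
    ct_input = 20.0
    rows = []
    for rep in range(1, cfg.qpcr_replicates + 1):
        for ctrl in ("control_A", "control_B"):
            rows.append({"site_id": ctrl, "replicate": rep,
                         "ct_ip": ct_input, "ct_input": ct_input,
                         "is_control": 1})
        for sid, le in zip(site_table["site_id"], log2e):
            rows.append({"site_id": sid, "replicate": rep,
                         "ct_ip": ct_input - le, "ct_input": ct_input,
                         "is_control": 0})
    truth = pd.DataFrame({
        "site_id": site_table["site_id"].to_numpy(),
        "occupancy_sd": occ,
        "log2_enrichment": log2e,
        "fold_enrichment": 2.0 ** log2e,
    })
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# profile archetypes for clustering recovery


def _archetype_profiles(length: int) -> dict[str, np.ndarray]:
    """Five canonical occupancy feature shapes (in vivo half catenated with
    in vitro half, values around a mean of 1): broad nucleosome-poor
    region, narrow NDR with phased flanks, a site occluded by a well-bound
    nucleosome, enriched flanking nucleosomes, and a flat (structureless)
    profile."""
    half = length // 2
    d = np.arange(half) - half // 2

    def pair(vivo, vitro):
        return np.concatenate([vivo, vitro])

    narrow = 1.0 - 0.7 * _gauss(d, 35.0)
    phased = narrow + 0.35 * np.cos(
        2 * np.pi * np.abs(d) / 165.0) * _gauss(np.abs(d) - 165, 220.0)
    broad_v = 1.0 - 0.45 * _gauss(d, 180.0)
    broad_t = 1.0 - 0.55 * _gauss(d, 250.0)
    occl_t = 1.0 + 0.9 * _gauss(d, 50.0) - 0.35 * _gauss(d, 350.0)
    flank = 1.0 - 0.3 * _gauss(d, 40.0) + 1.1 * _gauss(np.abs(d) - 120, 55.0)
    flat = np.ones(half)
    return {
        "broad_poor": pair(broad_v, broad_t),
        "narrow_ndr": pair(phased, narrow),
        "occluded_site": pair(narrow, occl_t),
        "flank_enriched": pair(flank, flank),
        "flat": pair(flat, flat),
    }


def simulate_profile_archetypes(
    n_per_cluster: int = 8,
    length: int = 1200,
    noise_sd: float = 0.08,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-TF profile features drawn from five planted archetypes.

    ``noise_sd`` (default 0.08, i.e. 8% of the mean occupancy) reflects the
    per-offset scatter of a profile averaged over a few dozen sites at
    ~10x depth, including site-to-site heterogeneity.

    Returns ``(X, labels, archetype_names)`` with X of shape
    (5 * n_per_cluster, length).
    """
    rng = _as_rng(seed)
    shapes = _archetype_profiles(length)
    names = list(shapes)
    X = []
    labels = []
    for i, name in enumerate(names):
        for _ in range(n_per_cluster):
            X.append(shapes[name] + rng.normal(0.0, noise_sd, size=length))
            labels.append(i)
    return np.asarray(X), np.asarray(labels), names


# ---------------------------------------------------------------------------
# one-call study bundle


@dataclass
class StudyBundle:
    """Everything one synthetic study produces."""

    config: SimConfig
    genome: GenomeSequence
    gene_starts: pd.DataFrame
    pwm: PwmRecord
    sites: pd.DataFrame          # includes ground-truth columns
    maps: dict[str, TagMap]      # invivo / invitro / xlink
    rates: dict[str, dict[str, np.ndarray]]
    tag_starts: pd.DataFrame     # explicit tags for the in vivo library
    qpcr: pd.DataFrame
    qpcr_truth: pd.DataFrame

    @property
    def truth(self) -> dict:
        """JSON-serializable ground truth sufficient to recompute every
        planted quantity."""
        return {
            "config": asdict(self.config),
            "sites": self.sites.to_dict(orient="records"),
            "qpcr": self.qpcr_truth.to_dict(orient="records"),
        }


def simulate_study(cfg: SimConfig | None = None, seed: int = 0) -> StudyBundle:
    """Run the full generator: genome, PWM, planted sites, three tag maps,
    explicit tag starts, and a qPCR table."""
    cfg = cfg if cfg is not None else SimConfig()
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(seed).spawn(6)]
    genome, gene_starts = generate_genome(cfg, streams[0])
    pwm = random_pwm(cfg.motif_length, streams[1], name=cfg.tf_name)
    genome, site_table = plant_sites(genome, gene_starts, pwm, cfg, streams[2])
    maps, rates = simulate_tag_maps(genome, site_table, cfg, streams[3])
    tag_starts = sample_tag_starts(rates["invivo"], streams[4])

    bound = site_table[site_table["bound"]]
    from .tagmap import site_center, window_average
    occ = np.array([
        window_average(maps["invivo"], row.chrom,
                       site_center(row.start, row.end), 15,
                       motif_even=(row.end - row.start) % 2 == 0)
        for row in bound.itertuples(index=False)
    ])
    sd = occ.std(ddof=0)
    occ_sd = (occ - occ.mean()) / sd if sd > 0 else np.zeros_like(occ)
    qpcr, qpcr_truth = simulate_qpcr(bound, occ_sd, cfg, streams[5])
    return StudyBundle(
        config=cfg, genome=genome, gene_starts=gene_starts, pwm=pwm,
        sites=site_table, maps=maps, rates=rates, tag_starts=tag_starts,
        qpcr=qpcr, qpcr_truth=qpcr_truth,
    )
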