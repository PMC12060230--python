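"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is a pure function of ``(cfg, seed)`` and returns a *truth*
record sufficient to score recovery tests without re-deriving parameters.
The defaults mirror the study design: a 305-line RIL panel built from 12
generations of intercrossing between one France and one Zambia strain
followed by 5 generations of inbreeding (ancestry tracts on the megabase
scale, residual heterozygosity ~0.5^5), ~19 retained song recordings per RIL
and ~43 per inbred strain, a 10 FR vs 7 ZI inbred strain panel scored for 37
correlated traits, and two-population haplotype panels with Balding-Nichols
divergence and an optional local sweep.

What is emulated vs not: the generators reproduce sample sizes, variance
components, trait correlation structure, ancestry-mosaic tract scale and
allele-frequency divergence -- not audio, assay-day effects, linkage
disequilibrium within windows, or inversion polymorphism.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from . import trait_io
from .popgen_scan import HaplotypePanel
from .annotate import Exon, GeneModel
from .qtl_scan import AncestryGenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QtlSpec:
    """A planted additive QTL: window index and effect as a fraction of the
    parental trait difference (the homozygote contrast 2*beta equals
    ``effect_fraction * |parent_fr - parent_zi|``)."""

    window: int
    effect_fraction: float


@dataclass
class SimConfig:
    """Study-condition parameters for every generator.

    RIL panel: 305 recombinant inbred lines over 5 chromosome arms; ancestry
    breakpoints accumulate for 12 intercross generations at ~2 cM/Mb, giving
    megabase-scale tracts; 5 generations of inbreeding leave ~3% residual
    heterozygosity per tract.  Trait scale defaults to the slow-to-total
    pulse fraction (parental means 0.745 vs 0.833); replicate and strain
    noise are on that scale.  Population panel: 10 FR vs 7 ZI strains, 37
    traits with block-exchangeable correlation.  Haplotype panels:
    Balding-Nichols divergence F between two panels of 20 haplotypes over
    200 x 5 kb windows with ~40 SNPs each.
    """

    # RIL ancestry panel
    n_rils: int = 305
    arms: tuple[str, ...] = ("X", "2L", "2R", "3L", "3R")
    arm_length_bp: int = 24_000_000
    windows_per_arm: int = 100
    intercross_generations: int = 12
    inbreeding_generations: int = 5
    recomb_rate: float = 2e-8        # crossovers / bp / meiosis (~2 cM/Mb)
    skewed_windows: tuple[int, ...] = ()
    skew_proportion: float = 0.97

    # RIL trait model
    qtls: tuple[QtlSpec, ...] = ()
    trait_name: str = "slow_pulse_fraction"
    parent_fr_value: float = 0.745
    parent_zi_value: float = 0.833
    strain_noise_sd: float = 0.03
    replicate_noise_sd: float = 0.10
    ril_replicates: int = 19
    inbred_replicates: int = 43
    heavy_tailed: bool = False       # t_5 replicate noise instead of Gaussian
    n_low_song: int = 0              # planted filter violations
    n_high_sine: int = 0

    # FR/ZI inbred population panel
    n_fr: int = 10
    n_zi: int = 7
    n_traits: int = 37
    pop_shift: float | tuple[float, ...] = 0.0   # delta per trait, FR minus ZI
    between_strain_sd: float = 1.0
    trait_block_size: int = 5
    trait_block_rho: float = 0.6

    # haplotype panels
    n_hap1: int = 20
    n_hap2: int = 20
    n_hap_windows: int = 200
    sites_per_window: int = 40
    hap_window_bp: int = 5_000
    bn_F: float = 0.2
    sweep_window: int | None = None
    sweep_fidelity: float = 0.98     # per-site copy probability in the sweep

    # gene models
    n_genes: int = 50
    max_exons: int = 10
    gene_lists: tuple[str, ...] = ("male_mating_behavior", "wing_disc", "nervous_system")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "qtls" in raw:
            raw["qtls"] = tuple(QtlSpec(**q) if isinstance(q, dict) else QtlSpec(*q)
                                for q in raw["qtls"])
        for key in ("arms", "skewed_windows", "gene_lists"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _window_frame(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    width = cfg.arm_length_bp // cfg.windows_per_arm
    for arm in cfg.arms:
        for i in range(cfg.windows_per_arm):
            rows.append((arm, i * width, (i + 1) * width))
    return pd.DataFrame(rows, columns=["arm", "start", "end"])


def simulate_ril_panel(cfg: SimConfig, seed: int | None = None
                       ) -> tuple[AncestryGenotypeMatrix, dict]:
    """Ancestry-mosaic RIL genotypes over genomic windows.

    Per RIL and arm, crossover breakpoints are a Poisson process with rate
    ``recomb_rate * intercross_generations`` per bp (tracts ~L/(g*c),
    megabase scale at g=12); tracts alternate parental ancestry from a
    random start.  Residual heterozygosity after inbreeding is a per-tract
    Bernoulli with rate 0.5^inbreeding_generations.  Windows inherit the
    dosage of the tract overlying their midpoint.  Optional skewed windows
    are forced toward FR ancestry in ``skew_proportion`` of lines.
    """
    if cfg.windows_per_arm < 1 or not cfg.arms:
        raise ValueError("config defines zero windows")
    rng = np.random.default_rng(seed)
    windows = _window_frame(cfg)
    het_rate = 0.5 ** cfg.inbreeding_generations
    break_rate = cfg.recomb_rate * cfg.intercross_generations * cfg.arm_length_bp
    mids = (windows["start"].values + windows["end"].values) // 2
    dosage = np.empty((cfg.n_rils, len(windows)))
    arm_index = {a: np.flatnonzero(windows["arm"].values == a) for a in cfg.arms}
    for r in range(cfg.n_rils):
        for arm in cfg.arms:
            cols = arm_index[arm]
            n_break = rng.poisson(break_rate)
            breaks = np.sort(rng.uniform(0, cfg.arm_length_bp, n_break))
            first = rng.integers(0, 2)
            tract_anc = (first + np.arange(n_break + 1)) % 2  # alternating FR/ZI
            tract_dose = np.where(rng.random(n_break + 1) < het_rate, 1, 2 * tract_anc)
            idx = np.searchsorted(breaks, mids[cols])
            dosage[r, cols] = tract_dose[idx]
    for w in cfg.skewed_windows:
        forced = rng.random(cfg.n_rils) < cfg.skew_proportion
        dosage[forced, w] = 2.0
        dosage[~forced, w] = rng.integers(0, 2, (~forced).sum()) * 2.0
    ril_ids = np.array([f"RIL{i:03d}" for i in range(cfg.n_rils)])
    truth = {"skewed_windows": list(cfg.skewed_windows), "het_rate": het_rate}
    return AncestryGenotypeMatrix(windows, dosage, ril_ids), truth


def simulate_ril_traits(
    panel: AncestryGenotypeMatrix, cfg: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, trait_io.StrainTraitTable, dict]:
    """Replicate recording records and strain trait means for a RIL panel.

    The strain genetic value is the sum over planted QTLs of
    ``beta * (dosage - 1)`` with ``2 beta = effect_fraction * (parent_fr -
    parent_zi)``; strain means sit at the parental midpoint plus genetic
    value plus strain-level noise; replicates add recording noise.  Filter
    violations (low song rate / aberrant sine totals) are planted on
    disjoint replicate sets for filter tests.
    """
    rng = np.random.default_rng(seed)
    delta = cfg.parent_fr_value - cfg.parent_zi_value
    genetic = np.zeros(panel.n_rils)
    betas = {}
    for q in cfg.qtls:
        if not 0 <= q.window < panel.n_windows:
            raise ValueError(f"QTL window {q.window} not in the panel")
        beta = q.effect_fraction * delta / 2.0
        betas[q.window] = beta
        genetic += beta * (np.nan_to_num(panel.dosage[:, q.window], nan=1.0) - 1.0)
    midpoint = (cfg.parent_fr_value + cfg.parent_zi_value) / 2.0
    strain_means = midpoint + genetic + rng.normal(0, cfg.strain_noise_sd, panel.n_rils)

    n_rep = cfg.ril_replicates
    rows = []
    for i, strain in enumerate(panel.ril_ids):
        if cfg.heavy_tailed:
            noise = rng.standard_t(5, n_rep) * cfg.replicate_noise_sd
        else:
            noise = rng.normal(0, cfg.replicate_noise_sd, n_rep)
        vals = strain_means[i] + noise
        song = np.clip(rng.normal(4.0, 1.0, n_rep), 1.0, None)
        sine = np.clip(rng.normal(20.0, 8.0, n_rep), 0.0, 55.0)
        for k in range(n_rep):
            rows.append((str(strain), "RIL", f"{strain}_r{k}", song[k], sine[k], vals[k]))
    records = pd.DataFrame(rows, columns=["strain", "cohort", "replicate",
                                          "song_per_min", "sine_total", cfg.trait_name])
    n_total = len(records)
    if cfg.n_low_song + cfg.n_high_sine > n_total:
        raise ValueError("more planted violations than recordings")
    viol = rng.choice(n_total, cfg.n_low_song + cfg.n_high_sine, replace=False)
    low, high = viol[: cfg.n_low_song], viol[cfg.n_low_song:]
    records.loc[records.index[low], "song_per_min"] = rng.uniform(0.0, 0.99, len(low))
    records.loc[records.index[high], "sine_total"] = rng.uniform(55.01, 90.0, len(high))
    retained, _ = trait_io.filter_recordings(records)
    table = trait_io.strain_trait_means(retained)
    truth = {
        "strain_means": dict(zip(map(str, panel.ril_ids), strain_means)),
        "genetic_values": genetic,
        "betas": betas,
        "qtl_windows": [q.window for q in cfg.qtls],
        "effect_fractions": {q.window: q.effect_fraction for q in cfg.qtls},
        "delta_parents": delta,
        "low_song_replicates": set(records.loc[records.index[low], "replicate"]),
        "high_sine_replicates": set(records.loc[records.index[high], "replicate"]),
    }
    return records, table, truth


def _block_correlation(n_traits: int, block: int, rho: float) -> np.ndarray:
    R = np.eye(n_traits)
    for s in range(0, n_traits, block):
        e = min(s + block, n_traits)
        R[s:e, s:e] = rho
    np.fill_diagonal(R, 1.0)
    return R


def _nearest_pd(R: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(R)
    if w.min() > 1e-10:
        return R
    logger.warning("correlation matrix not positive definite; clipping eigenvalues")
    w = np.clip(w, 1e-8, None)
    R2 = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(R2))
    return R2 / np.outer(d, d)


def simulate_population_panel(cfg: SimConfig, seed: int | None = None
                              ) -> tuple[trait_io.StrainTraitTable, dict]:
    """FR/ZI strain-mean table with correlated traits and a population shift.

    Strain means are multivariate normal with a block-exchangeable trait
    correlation matrix; each trait's population shift delta (FR minus ZI) is
    split +/- delta/2 around zero, so delta = 0 gives the exchangeable null
    used for family-wise FPR calibration.
    """
    rng = np.random.default_rng(seed)
    T = cfg.n_traits
    delta = np.broadcast_to(np.asarray(cfg.pop_shift, dtype=float), (T,)).copy()
    R = _nearest_pd(_block_correlation(T, cfg.trait_block_size, cfg.trait_block_rho))
    L = np.linalg.cholesky(R)
    n = cfg.n_fr + cfg.n_zi
    z = rng.standard_normal((n, T))
    means = z @ L.T * cfg.between_strain_sd
    means[: cfg.n_fr] += delta / 2.0
    means[cfg.n_fr:] -= delta / 2.0
    strains = [f"FR{i:02d}" for i in range(cfg.n_fr)] + [f"ZI{i:02d}" for i in range(cfg.n_zi)]
    traits = [f"trait_{j + 1:02d}" for j in range(T)]
    means_df = pd.DataFrame(means, index=pd.Index(strains, name="strain"), columns=traits)
    counts = pd.DataFrame(cfg.inbred_replicates, index=means_df.index, columns=traits)
    cohort = pd.Series(["FR"] * cfg.n_fr + ["ZI"] * cfg.n_zi, index=means_df.index)
    truth = {"delta": delta, "correlation": R}
    return trait_io.StrainTraitTable(means_df, counts, cohort), truth


def simulate_haplotypes(cfg: SimConfig, seed: int | None = None
                        ) -> tuple[HaplotypePanel, HaplotypePanel, pd.DataFrame, dict]:
    """Two diverged haplotype panels with an optional local sweep.

    Per site, an ancestral frequency is drawn uniformly on (0.05, 0.95) and
    the two population frequencies follow the Balding-Nichols model with
    divergence parameter F; haplotypes sample alleles independently.  In the
    sweep window (if any) population 1's haplotypes are replaced by copies
    of a single template with per-site copy fidelity ``sweep_fidelity``.
    """
    rng = np.random.default_rng(seed)
    n_sites = cfg.n_hap_windows * cfg.sites_per_window
    length = cfg.n_hap_windows * cfg.hap_window_bp
    positions = np.sort(rng.choice(np.arange(1, length + 1), n_sites, replace=False))
    p_anc = rng.uniform(0.05, 0.95, n_sites)
    F = cfg.bn_F
    if F <= 0:
        p1 = p2 = p_anc
    else:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p1 = rng.beta(a, b)
        p2 = rng.beta(a, b)
    H1 = (rng.random((cfg.n_hap1, n_sites)) < p1).astype(np.int8)
    H2 = (rng.random((cfg.n_hap2, n_sites)) < p2).astype(np.int8)
    windows = pd.DataFrame({
        "arm": "3R",
        "start": np.arange(cfg.n_hap_windows) * cfg.hap_window_bp,
        "end": (np.arange(cfg.n_hap_windows) + 1) * cfg.hap_window_bp,
    })
    if cfg.sweep_window is not None:
        w = cfg.sweep_window
        lo = int(np.searchsorted(positions, windows["start"].iloc[w] + 1))
        hi = int(np.searchsorted(positions, windows["end"].iloc[w], side="right"))
        template = (rng.random(hi - lo) < p1[lo:hi]).astype(np.int8)
        copy = rng.random((cfg.n_hap1, hi - lo)) < cfg.sweep_fidelity
        H1[:, lo:hi] = np.where(copy, template[None, :], 1 - template[None, :])
    truth = {"sweep_window": cfg.sweep_window, "p1": p1, "p2": p2, "F": F}
    return (HaplotypePanel(H1, positions, "3R"),
            HaplotypePanel(H2, positions, "3R"), windows, truth)


def simulate_genes(cfg: SimConfig, seed: int | None = None
                   ) -> tuple[list[GeneModel], dict[str, set[str]], dict]:
    """Non-overlapping gene models with planted candidate-list memberships."""
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    pos = 1000
    for i in range(cfg.n_genes):
        n_ex = int(rng.integers(1, cfg.max_exons + 1))
        exons = []
        p = pos
        for _ in range(n_ex):
            length = int(rng.integers(100, 800))
            exons.append(Exon(p, p + length, bool(rng.random() < 0.7)))
            p += length + int(rng.integers(50, 500))
        if not any(e.coding for e in exons):  # ensure >=1 coding exon
            exons[0] = Exon(exons[0].start, exons[0].end, True)
        gid = f"SG{i:04d}"
        genes.append(GeneModel(gid, f"sg-{i}", "3R",
                               "+" if rng.random() < 0.5 else "-", tuple(exons)))
        pos = p + int(rng.integers(500, 3000))
    lists: dict[str, set[str]] = {}
    ids = [g.gene_id for g in genes]
    for name in cfg.gene_lists:
        k = max(1, cfg.n_genes // 10)
        lists[name] = set(rng.choice(ids, k, replace=False)) if ids else set()
    truth = {"memberships": {name: set(v) for name, v in lists.items()}}
    return genes, lists, truth
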