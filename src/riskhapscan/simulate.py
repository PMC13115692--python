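"""Forward simulator for a two-lineage cohort in which one founder chromosome
carrying a rare risk allele expands over g generations under recombination.

The model is a diploid Wright-Fisher population with non-overlapping
generations, random mating within lineage, symmetric migration between the
two lineages, and a parent-sampling weight on risk-allele carriers
(``carrier_advantage``) that emulates the demographic amplification
(popular-sire effects, drift in small pools) by which a rare haplotype can
rise in frequency in one lineage within ~11 generations. Recombination
follows a linear genetic map: per meiosis the number of crossovers is
Poisson with rate ``recomb_rate_cM_per_Mb * span_Mb / 100`` and positions
are uniform over the region.

Every final haplotype is a mosaic of founder chromosomes tracked exactly as
ancestry tracts, so the simulator emits, besides phased genotypes and
phenotypes, the *true* identity-by-descent segments that an IBD detector
would ideally recover. Phenotypes follow a dosage-dependent logistic
penetrance model; case onset ages follow a Weibull hazard with a male
effect and a time-varying gonadectomy effect switching at the gonadectomy
age (when it precedes the landmark age).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CohortTable,
    FocalMarkerSpec,
    IBDSegmentSet,
    MarkerMap,
    PhasedHaplotypeSet,
    linear_genetic_map,
    write_ibd_segments,
    write_phased_vcf,
    write_phenotypes,
)

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "SimulatedDataset",
    "simulate_haplotypes",
    "simulate_phenotypes",
    "simulate_cohort",
    "simulate_survival_cohort",
    "emit",
]

_ACGT = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; the seed is mandatory.

    Defaults emulate the study conditions: a ~170-dog two-lineage cohort, a
    single founder risk chromosome introduced g = 11 generations ago on a
    1 cM/Mb map, dosage-dependent penetrance with all dosage-2 dogs
    affected in expectation (per-allele log-OR 1.9 over a baseline of
    -1.55), controls at least 7.5 years old, and sex/gonadectomy onset
    modifiers. Effective lineage sizes (200/200) and migration (0.01) are
    placeholders to vary in experiments, not estimates.
    """

    seed: int
    n_markers: int = 1200
    chromosome: str = "3"
    region_start_bp: int = 71_000_000
    region_span_bp: int = 36_000_000
    focal_bp: int = 88_803_651
    recomb_rate_cM_per_Mb: float = 1.0
    g_generations: int = 11
    pop_size: dict = field(default_factory=lambda: {"ShowPet": 500, "Working": 200})
    n_dogs: dict = field(default_factory=lambda: {"ShowPet": 100, "Working": 70})
    migration_rate: float = 0.01
    founder_risk_copies: int = 1
    founder_expansion_weight: float = 80.0
    founder_expansion_generations: int = 1
    carrier_advantage: float = 0.05
    base_alt_freq_beta: tuple = (0.8, 0.8)
    baseline_log_odds: float = -1.55
    per_allele_log_OR: float = 1.9
    male_log_HR: float = float(np.log(3.0))
    gonadectomy_log_HR: float = float(np.log(2.7))
    landmark_years: float = 5.0
    onset_weibull_shape: float = 2.0
    onset_hazard_scale: float = 4.0
    frac_male: float = 0.56
    frac_gonadectomized: float = 0.5
    gonadectomy_age_range: tuple = (0.5, 6.0)
    control_min_age: float = 7.5
    max_followup_age: float = 14.0
    frac_sanger: float = 0.0
    max_retries: int = 25

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.recomb_rate_cM_per_Mb < 0 or self.migration_rate < 0:
            raise ValueError("rates must be non-negative")
        if not (0 <= self.migration_rate <= 1 and 0 <= self.frac_male <= 1
                and 0 <= self.frac_gonadectomized <= 1
                and 0 <= self.frac_sanger <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if not (self.region_start_bp <= self.focal_bp
                < self.region_start_bp + self.region_span_bp):
            raise ValueError("focal position outside the region")

    @property
    def region_end_bp(self) -> int:
        return self.region_start_bp + self.region_span_bp


@dataclass
class SimulatedTruth:
    """Ground truth recorded by the simulator.

    ``descent_tracts[h]`` lists the disjoint bp intervals (half-open,
    absolute coordinates) of haplotype ``h`` inherited from a risk founder
    chromosome; every risk-allele copy lies inside such a tract.
    ``ancestry[h]`` is the full founder mosaic as ``(starts, founder_ids)``.
    """

    focal_index: int
    risk_founder_ids: tuple
    descent_tracts: list
    ancestry: list
    carrier_dog: np.ndarray
    attempt: int
    config: SimulationConfig


@dataclass
class SimulatedDataset:
    marker_map: MarkerMap
    haplotypes: PhasedHaplotypeSet
    truth: SimulatedTruth
    cohort: CohortTable

    @property
    def focal_spec(self) -> FocalMarkerSpec:
        mm = self.marker_map
        j = self.truth.focal_index
        return FocalMarkerSpec(
            marker_id=str(mm.marker_id[j]),
            risk_allele=str(mm.alt_allele[j]),
            interval_start_bp=int(mm.position_bp[0]),
            interval_end_bp=int(mm.position_bp[-1]),
        )


# ---------------------------------------------------------------------------
# Ancestry-tract machinery
# ---------------------------------------------------------------------------

def _splice(hap_a, hap_b, breaks, first):
    """Gamete from two parental mosaics given crossover positions.

    A mosaic is ``(starts, fids)`` with ``starts[0]`` = region start; tract i
    covers ``[starts[i], starts[i+1])``.
    """
    if not breaks:
        return hap_a if first == 0 else hap_b
    source = (hap_a, hap_b)
    out_s, out_f = [], []
    cur = first
    prev = None
    bounds = list(breaks)
    for k in range(len(bounds) + 1):
        a = source[cur][0][0] if prev is None else prev
        b = bounds[k] if k < len(bounds) else None
        starts, fids = source[cur]
        i = bisect.bisect_right(starts, a) - 1
        while i < len(starts) and (b is None or starts[i] < b):
            s = max(starts[i], a)
            f = fids[i]
            if out_f and out_f[-1] == f:
                pass  # merge with previous tract of same founder
            else:
                out_s.append(s)
                out_f.append(f)
            i += 1
        prev = b
        cur = 1 - cur
    return (out_s, out_f)


def _founder_at(hap, pos):
    starts, fids = hap
    return fids[bisect.bisect_right(starts, pos) - 1]


def _simulate_ancestry(config: SimulationConfig, rng):
    """One Wright-Fisher run; returns per-lineage final individuals as
    ancestry mosaics plus founder bookkeeping."""
    lineages = [name for name, n in config.pop_size.items() if n > 0]
    sizes = {k: int(config.pop_size[k]) for k in lineages}
    start, end = config.region_start_bp, config.region_end_bp

    # founder haplotypes: identity mosaics with globally unique ids
    next_id = 0
    pops = {}
    founder_ids = {}
    for lin in lineages:
        inds = []
        ids = []
        for _ in range(sizes[lin]):
            h1 = ([start], [next_id]); ids.append(next_id); next_id += 1
            h2 = ([start], [next_id]); ids.append(next_id); next_id += 1
            inds.append((h1, h2))
        pops[lin] = inds
        founder_ids[lin] = ids
    n_founders = next_id

    # the risk founder chromosome(s) sit in the first lineage
    risk = tuple(founder_ids[lineages[0]][: config.founder_risk_copies])
    risk_set = set(risk)

    rate = config.recomb_rate_cM_per_Mb * (config.region_span_bp / 1e6) / 100.0

    def carrier_weights(inds, advantage):
        w = np.ones(len(inds))
        if advantage:
            for i, (h1, h2) in enumerate(inds):
                if (_founder_at(h1, config.focal_bp) in risk_set
                        or _founder_at(h2, config.focal_bp) in risk_set):
                    w[i] += advantage
        return w / w.sum()

    for gen in range(config.g_generations):
        # front-loaded amplification: a popular-sire-style burst in the first
        # generations after introduction, mild advantage afterwards
        adv = (config.founder_expansion_weight
               if gen < config.founder_expansion_generations
               else config.carrier_advantage)
        weights = {lin: carrier_weights(pops[lin], adv) for lin in lineages}
        new_pops = {}
        for lin in lineages:
            n = sizes[lin]
            other = [l for l in lineages if l != lin]
            # per child, two parents; each migrates independently
            migrate = (rng.random((n, 2)) < config.migration_rate) if other else \
                np.zeros((n, 2), dtype=bool)
            n_breaks = rng.poisson(rate, size=(n, 2))
            firsts = rng.integers(0, 2, size=(n, 2))
            children = []
            for i in range(n):
                gametes = []
                for p in range(2):
                    src = other[0] if migrate[i, p] else lin
                    j = rng.choice(len(pops[src]), p=weights[src])
                    parent = pops[src][j]
                    k = int(n_breaks[i, p])
                    if k:
                        breaks = np.sort(
                            rng.integers(start + 1, end, size=k)
                        ).tolist()
                    else:
                        breaks = []
                    gametes.append(
                        _splice(parent[0], parent[1], breaks, int(firsts[i, p]))
                    )
                children.append((gametes[0], gametes[1]))
            new_pops[lin] = children
        pops = new_pops

    return pops, n_founders, risk, lineages


def simulate_haplotypes(config: SimulationConfig):
    """Run the forward simulation and materialize phased haplotypes.

    Returns ``(MarkerMap, PhasedHaplotypeSet, SimulatedTruth)``. If the risk
    allele is absent from the sampled cohort (lost by drift), the run is
    retried with a derived seed up to ``max_retries`` times; the attempt
    number is recorded in the truth object.
    """
    last_err = None
    for attempt in range(config.max_retries + 1):
        rng = np.random.default_rng([int(config.seed), attempt])
        out = _attempt_haplotypes(config, rng, attempt)
        if out is not None:
            return out
        last_err = attempt
    raise RuntimeError(
        f"risk allele lost by drift in all {config.max_retries + 1} attempts "
        f"(seed {config.seed}, last attempt {last_err})"
    )


def _attempt_haplotypes(config, rng, attempt):
    start, end = config.region_start_bp, config.region_end_bp

    # marker map: uniform positions plus the focal marker exactly
    while True:
        pos = np.unique(rng.integers(start, end, size=config.n_markers - 1))
        if len(pos) == config.n_markers - 1 and config.focal_bp not in pos:
            break
    positions = np.sort(np.append(pos, config.focal_bp))
    focal_index = int(np.searchsorted(positions, config.focal_bp))
    ids = np.array([f"M{p}" for p in positions], dtype=object)
    ids[focal_index] = "LEAD"
    ref = _ACGT[rng.integers(0, 4, size=config.n_markers)]
    shift = rng.integers(1, 4, size=config.n_markers)
    alt = _ACGT[(np.searchsorted(_ACGT, ref) + shift) % 4]
    ref[focal_index], alt[focal_index] = "G", "A"
    mm = MarkerMap(ids, config.chromosome, positions, ref, alt)

    pops, n_founders, risk, lineages = _simulate_ancestry(config, rng)

    # founder allele matrix
    a, b = config.base_alt_freq_beta
    freqs = rng.beta(a, b, size=config.n_markers)
    founder_alleles = (
        rng.random((n_founders, config.n_markers)) < freqs
    ).astype(np.uint8)
    founder_alleles[:, focal_index] = 0
    for fid in risk:
        founder_alleles[fid, focal_index] = 1

    # sample dogs
    prefix = {"ShowPet": "SP", "Working": "WK"}
    dogs, hap_mosaics = [], []
    for lin in lineages:
        n = int(config.n_dogs.get(lin, 0))
        if n > len(pops[lin]):
            raise ValueError(f"cannot sample {n} dogs from {len(pops[lin])} in {lin}")
        pick = rng.choice(len(pops[lin]), size=n, replace=False)
        for k, j in enumerate(sorted(pick.tolist())):
            dog = f"{prefix.get(lin, lin[:2].upper())}{k + 1:04d}"
            dogs.append((dog, lin))
            hap_mosaics.append(pops[lin][j][0])
            hap_mosaics.append(pops[lin][j][1])

    # materialize alleles from ancestry tracts
    H = len(hap_mosaics)
    alleles = np.empty((H, config.n_markers), dtype=np.uint8)
    risk_set = set(risk)
    descent = []
    for h, (starts, fids) in enumerate(hap_mosaics):
        bounds = starts + [end]
        tracts = []
        for i, fid in enumerate(fids):
            i0 = np.searchsorted(positions, bounds[i], side="left")
            i1 = np.searchsorted(positions, bounds[i + 1], side="left")
            if i1 > i0:
                alleles[h, i0:i1] = founder_alleles[fid, i0:i1]
            if fid in risk_set:
                # adjacent mosaic tracts always stem from different founders
                # (same-founder contiguity is merged at gamete formation), so
                # each risk tract is one founder's descent interval
                tracts.append((bounds[i], bounds[i + 1]))
        descent.append(tracts)

    hap_ids = [(d, side) for d, _lin in dogs for side in (1, 2)]
    haps = PhasedHaplotypeSet(hap_ids, alleles, mm)

    col = alleles[:, focal_index]
    if col.sum() == 0:
        return None  # lost by drift; caller retries
    carrier_dog = (col[0::2] + col[1::2]) > 0

    truth = SimulatedTruth(
        focal_index=focal_index,
        risk_founder_ids=risk,
        descent_tracts=descent,
        ancestry=hap_mosaics,
        carrier_dog=carrier_dog,
        attempt=attempt,
        config=config,
    )
    truth._lineages = [lin for _d, lin in dogs]
    truth._dog_ids = [d for d, _lin in dogs]
    return mm, haps, truth


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _invert_onset(E, male, gon_age, cfg: SimulationConfig):
    """Invert the piecewise cumulative Weibull hazard for one dog.

    H(t) = exp(bm*male) * [H0(min(t, a)) + exp(bg) * (H0(t) - H0(a))]_{t>a}
    with the exposure switch at a = gonadectomy age (inf when unexposed).
    """
    k, lam = cfg.onset_weibull_shape, cfg.onset_hazard_scale

    def H0(t):
        return (t / lam) ** k

    def H0inv(u):
        return lam * u ** (1.0 / k)

    mult = np.exp(cfg.male_log_HR * male)
    e = E / mult
    if not np.isfinite(gon_age):
        return H0inv(e)
    if e <= H0(gon_age):
        return H0inv(e)
    rg = np.exp(cfg.gonadectomy_log_HR)
    return H0inv(H0(gon_age) + (e - H0(gon_age)) / rg)


def simulate_phenotypes(haps: PhasedHaplotypeSet, truth: SimulatedTruth,
                        config: SimulationConfig | None = None) -> CohortTable:
    """Draw case/control status and covariates given simulated genotypes.

    Case probability is ``logistic(baseline + per_allele_log_OR * dosage)``
    at the focal marker; case onset ages come from the modifier hazard
    model; controls are seizure-free dogs followed to at least
    ``control_min_age`` years.
    """
    cfg = config or truth.config
    rng = np.random.default_rng([int(cfg.seed), truth.attempt, 7])
    focal = truth.focal_index
    col = haps.alleles[:, focal].astype(int)
    dosage = col[0::2] + col[1::2]
    n = len(dosage)
    dog_ids = getattr(truth, "_dog_ids", [d for d, _s in haps.haplotype_ids[::2]])
    lin_groups = getattr(truth, "_lineages", ["ShowPet"] * n)
    lineage_pick = {
        "ShowPet": np.array(["show", "pet", "sled-show", "husky-mix"]),
        "Working": np.array(["racing", "seppala"]),
    }

    p_case = 1.0 / (1.0 + np.exp(-(cfg.baseline_log_odds
                                   + cfg.per_allele_log_OR * dosage)))
    is_case = rng.random(n) < p_case
    male = rng.random(n) < cfg.frac_male
    gonadectomized = rng.random(n) < cfg.frac_gonadectomized
    g_lo, g_hi = cfg.gonadectomy_age_range
    gon_age = np.where(gonadectomized, rng.uniform(g_lo, g_hi, size=n), np.nan)

    rows = []
    for i in range(n):
        lin = rng.choice(lineage_pick.get(lin_groups[i], lineage_pick["ShowPet"]))
        exposure_switch = (
            gon_age[i]
            if gonadectomized[i] and gon_age[i] < cfg.landmark_years
            else np.inf
        )
        if is_case[i]:
            onset = _invert_onset(rng.exponential(), int(male[i]),
                                  exposure_switch, cfg)
            onset = float(np.clip(onset, 0.25, 12.0))
            followup = onset + float(rng.uniform(0.5, 4.0))
        else:
            onset = np.nan
            followup = float(rng.uniform(cfg.control_min_age,
                                         cfg.max_followup_age))
        rows.append(dict(
            dog_id=dog_ids[i],
            status="case" if is_case[i] else "control",
            sex="M" if male[i] else "F",
            lineage=str(lin),
            cohort_label=("Sanger" if rng.random() < cfg.frac_sanger else "GWAS"),
            age_onset_years=onset,
            age_last_followup_years=followup,
            age_gonadectomy_years=float(gon_age[i]) if gonadectomized[i] else np.nan,
            gonadal_status=("gonadectomized" if gonadectomized[i] else "intact"),
        ))
    return CohortTable(pd.DataFrame(rows))


def simulate_cohort(config: SimulationConfig) -> SimulatedDataset:
    """Full pipeline input: haplotypes + truth + phenotypes."""
    mm, haps, truth = simulate_haplotypes(config)
    cohort = simulate_phenotypes(haps, truth, config)
    return SimulatedDataset(mm, haps, truth, cohort)


def simulate_survival_cohort(
    n: int,
    seed: int,
    male_log_HR: float = 0.0,
    gonadectomy_log_HR: float = 0.0,
    landmark_years: float = 5.0,
    weibull_shape: float = 2.0,
    hazard_scale: float = 4.0,
    frac_male: float = 0.5,
    frac_gonadectomized: float = 0.5,
    censor_age: float = 10.0,
) -> CohortTable:
    """A pure time-to-onset cohort for survival-model calibration studies.

    Every dog follows the Weibull onset hazard with the stated sex and
    time-varying gonadectomy effects; dogs whose latent onset exceeds
    ``censor_age`` are seizure-free controls censored there. Unlike
    :func:`simulate_phenotypes` there is no case/control ascertainment
    layer, so the configured hazard ratios are exactly the estimands of a
    time-varying Cox fit.
    """
    cfg = SimulationConfig(
        seed=seed, male_log_HR=male_log_HR, gonadectomy_log_HR=gonadectomy_log_HR,
        landmark_years=landmark_years, onset_weibull_shape=weibull_shape,
        onset_hazard_scale=hazard_scale,
    )
    rng = np.random.default_rng([int(seed), 23])
    male = rng.random(n) < frac_male
    gonadectomized = rng.random(n) < frac_gonadectomized
    gon_age = np.where(gonadectomized, rng.uniform(0.5, 6.0, size=n), np.nan)
    rows = []
    for i in range(n):
        switch = (gon_age[i] if gonadectomized[i]
                  and gon_age[i] < landmark_years else np.inf)
        t = _invert_onset(rng.exponential(), int(male[i]), switch, cfg)
        event = t <= censor_age
        rows.append(dict(
            dog_id=f"D{i + 1:05d}",
            status="case" if event else "control",
            sex="M" if male[i] else "F",
            lineage="show",
            cohort_label="GWAS",
            age_onset_years=float(t) if event else np.nan,
            age_last_followup_years=float(t) if event else float(censor_age),
            age_gonadectomy_years=(float(gon_age[i]) if gonadectomized[i]
                                   else np.nan),
            gonadal_status=("gonadectomized" if gonadectomized[i] else "intact"),
        ))
    return CohortTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Emission of files (round-trips through the cohort_io readers)
# ---------------------------------------------------------------------------

def true_ibd_segments(dataset: SimulatedDataset, min_cM: float = 0.5,
                      min_markers: int = 0) -> IBDSegmentSet:
    """Pairwise true IBD segments: overlaps of same-founder ancestry tracts
    between sampled haplotypes, filtered to ``min_cM`` (and optionally a
    minimum marker count), in the hap-IBD dialect of the readers."""
    truth = dataset.truth
    mm = dataset.marker_map
    hap_ids = dataset.haplotypes.haplotype_ids
    by_founder = {}
    for h, (starts, fids) in enumerate(truth.ancestry):
        bounds = starts + [truth.config.region_end_bp]
        for i, fid in enumerate(fids):
            by_founder.setdefault(fid, []).append((h, bounds[i], bounds[i + 1]))
    rows = []
    for fid, tracts in by_founder.items():
        for i in range(len(tracts)):
            hi, si, ei = tracts[i]
            for j in range(i + 1, len(tracts)):
                hj, sj, ej = tracts[j]
                if hi == hj:
                    continue
                s, e = max(si, sj), min(ei, ej)
                if e <= s:
                    continue
                length = linear_genetic_map(e - s)
                if length < min_cM:
                    continue
                if min_markers:
                    k = (np.searchsorted(mm.position_bp, e)
                         - np.searchsorted(mm.position_bp, s))
                    if k < min_markers:
                        continue
                da, sa = hap_ids[hi]
                db, sb = hap_ids[hj]
                rows.append(dict(
                    dog_a=da, side_a=sa, dog_b=db, side_b=sb,
                    chromosome=mm.chromosome, start_bp=int(s), end_bp=int(e - 1),
                    length_cM=float(length),
                ))
    df = pd.DataFrame(rows, columns=list(IBDSegmentSet.COLUMNS))
    # merge multiple overlaps of the same pair+interval? multiple segments per
    # pair are allowed, mirroring hap-IBD output
    return IBDSegmentSet(df)


def emit(dataset: SimulatedDataset, out_dir, min_cM: float = 0.5) -> dict:
    """Write phased VCF, phenotype table, and true-IBD TSV; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "phenotypes": out / "phenotypes.csv",
        "ibd": out / "true_ibd.tsv",
    }
    write_phased_vcf(paths["vcf"], dataset.marker_map, dataset.haplotypes)
    write_phenotypes(paths["phenotypes"], dataset.cohort)
    write_ibd_segments(paths["ibd"], true_ibd_segments(dataset, min_cM=min_cM))
    return paths
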