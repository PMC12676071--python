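"""Synthetic single-pollen-nucleus cohorts with full ground truth.

The generator emulates the data-generating process the analysis assumes:

* a rye-like genome of 7 chromosomes of 730-960 Mb (so 10% windows span
  73-96 Mb), with array markers placed uniformly per chromosome;
* diploid parents heterozygous at a fraction of markers (defaults give about
  4300 informative markers per individual);
* meiotic crossovers per chromatid placed by a stationary gamma renewal
  process along relative chromosome length with mean ``lambda_cc`` per
  chromosome and shape ``nu`` (``nu = 1`` is the no-interference Poisson
  case; larger ``nu`` spaces crossovers more evenly);
* gametes as haplotype mosaics, genotyped with symmetric allele-flip error
  and random missingness; a fraction of nuclei fail amplification and are
  almost entirely missing (they should be removed by QC);
* a cohort design of two subpopulations x two treatments, with nutrient
  deficiency reducing the crossover rate by a multiplicative ``delta``.

Every stochastic choice is recorded in :class:`SimTruth`, which is sufficient
to recompute each downstream expected output; in particular
:func:`expected_detectable_events` derives, directly from the true crossover
positions, the events that the window/gap calling rules can possibly detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._codes import HET, MISSING
from .crossover import CrossoverConfig
from .genotype_io import GenotypeMatrix, MarkerMap, write_genotype_table

__all__ = [
    "SimConfig",
    "SimTruth",
    "Cohort",
    "sample_crossover_positions",
    "simulate_meiosis",
    "simulate_cohort",
    "expected_detectable_events",
]

_CHROM_NAMES = [f"{i}R" for i in range(1, 8)]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the scale of the single-pollen-nuclei study design:
    584 individuals in two subpopulations and two treatments, six nuclei per
    individual, 2.2 crossovers per chromatid, ~0.3% genotyping error and 5%
    missing calls, a 15% nucleus amplification-failure rate, and an 8%
    crossover reduction under nutrient deficiency.
    """

    n_chromosomes: int = 7
    chrom_lengths_mb: tuple = (730, 890, 900, 860, 880, 920, 960)
    n_markers_per_chrom: int = 875
    heterozygosity: float = 0.7
    n_individuals: int = 584
    nuclei_per_individual: int = 6
    lambda_cc: float = 2.2
    interference_nu: float = 5.0
    obligate_co: bool = False
    nd_effect_delta: float = 0.08
    missing_rate: float = 0.05
    error_rate: float = 0.003
    nucleus_failure_rate: float = 0.15
    failed_missing_rate: float = 0.95
    diversity_fraction: float = 310 / 675  # study's genotyped subpopulation split
    n_effect_alleles: int = 0
    allele_effect: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.chrom_lengths_mb) != self.n_chromosomes:
            raise ValueError("chrom_lengths_mb must have n_chromosomes entries")
        for name in ("heterozygosity", "missing_rate", "error_rate", "nucleus_failure_rate",
                     "failed_missing_rate", "nd_effect_delta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.lambda_cc <= 0 or self.interference_nu <= 0:
            raise ValueError("lambda_cc and interference_nu must be positive")

    @property
    def chromosomes(self) -> list[str]:
        return _CHROM_NAMES[: self.n_chromosomes]


def sample_crossover_positions(
    rng: np.random.Generator,
    lam: float,
    nu: float,
    n_chromatids: int,
    obligate: bool = False,
    max_attempts: int = 1000,
) -> list[np.ndarray]:
    """Crossover positions on [0, 1) for ``n_chromatids`` chromatids.

    Stationary gamma renewal process with mean rate ``lam`` per unit length
    and shape ``nu``: inter-crossover gaps are Gamma(nu, 1/(lam*nu)) and the
    first point is drawn from the equilibrium forward-recurrence distribution
    (uniform fraction of a length-biased gap), so ``nu = 1`` reduces exactly
    to a homogeneous Poisson process.
    """
    scale = 1.0 / (lam * nu)
    k0 = int(np.ceil(lam + 8.0 * np.sqrt(max(lam, 1.0)) + 10))
    first = rng.uniform(size=n_chromatids) * rng.gamma(nu + 1.0, scale, size=n_chromatids)
    gaps = rng.gamma(nu, scale, size=(n_chromatids, k0))
    pos = np.concatenate([first[:, None], first[:, None] + np.cumsum(gaps, axis=1)], axis=1)
    while (pos[:, -1] < 1.0).any():  # rare tail: extend short rows
        short = pos[:, -1] < 1.0
        extra = rng.gamma(nu, scale, size=(int(short.sum()), k0))
        ext = pos[short, -1][:, None] + np.cumsum(extra, axis=1)
        grown = np.full((pos.shape[0], pos.shape[1] + k0), np.inf)
        grown[:, : pos.shape[1]] = pos
        grown[short, pos.shape[1]:] = ext
        pos = grown
    out = [row[row < 1.0].copy() for row in pos]
    if obligate:
        for i in range(n_chromatids):
            attempts = 0
            while len(out[i]) == 0:
                attempts += 1
                if attempts > max_attempts:
                    raise RuntimeError("obligate crossover infeasible at this lambda")
                out[i] = sample_crossover_positions(rng, lam, nu, 1)[0]
    return out


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    hap1: dict = field(default_factory=dict)  # individual -> (M,) int8 haplotype-1 alleles
    het_mask: dict = field(default_factory=dict)  # individual -> (M,) bool
    crossovers: dict = field(default_factory=dict)  # nucleus -> {chrom: positions array}
    start_hap: dict = field(default_factory=dict)  # nucleus -> {chrom: 0|1}
    error_mask: dict = field(default_factory=dict)  # nucleus -> (M,) bool
    missing_mask: dict = field(default_factory=dict)  # nucleus -> (M,) bool
    failed_nuclei: set = field(default_factory=set)
    lambda_by_individual: dict = field(default_factory=dict)

    def true_co_counts(self) -> pd.DataFrame:
        rows = [
            {"nucleus_id": nuc, "chromosome": c, "n_true": len(p)}
            for nuc, per_chrom in self.crossovers.items()
            for c, p in per_chrom.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class Cohort:
    """A simulated study bundle in exactly the formats the readers accept."""

    config: SimConfig
    marker_map: MarkerMap
    gametes: GenotypeMatrix  # haploid, all nuclei pre-QC
    diploid: GenotypeMatrix
    meta: pd.DataFrame
    nuclei_of: dict
    truth: SimTruth
    allele_indicators: pd.DataFrame | None = None

    def write_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genotype_table(self.gametes, outdir / "gametes.csv")
        write_genotype_table(self.diploid, outdir / "diploid.csv")
        self.marker_map.to_files(outdir / "marker_map.csv", outdir / "chrom_lengths.csv")
        self.meta.to_csv(outdir / "metadata.csv", index=False)
        pd.DataFrame(
            [(n, i) for i, ns in self.nuclei_of.items() for n in ns],
            columns=["nucleus_id", "individual_id"],
        ).to_csv(outdir / "nuclei.csv", index=False)
        cfg = pd.Series({k: str(v) for k, v in self.config.__dict__.items()})
        cfg.to_csv(outdir / "sim_config.csv", header=False)


def _simulate_marker_map(cfg: SimConfig, rng: np.random.Generator) -> MarkerMap:
    rows = []
    lengths = {}
    for chrom, mb in zip(cfg.chromosomes, cfg.chrom_lengths_mb):
        length_bp = int(mb * 1e6)
        lengths[chrom] = length_bp
        pos = np.unique(rng.integers(1, length_bp + 1, size=cfg.n_markers_per_chrom))
        while len(pos) < cfg.n_markers_per_chrom:  # bp collisions are vanishingly rare
            extra = rng.integers(1, length_bp + 1, size=cfg.n_markers_per_chrom - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        for j, p in enumerate(pos):
            rows.append({"marker_id": f"{chrom}_m{j:05d}", "chromosome": chrom,
                         "position_bp": int(p)})
    return MarkerMap(pd.DataFrame(rows), lengths)


def simulate_meiosis(
    cfg: SimConfig,
    rng: np.random.Generator,
    marker_map: MarkerMap,
    individual_id: str,
    lam: float | None = None,
) -> tuple[np.ndarray, np.ndarray, SimTruth]:
    """Simulate one individual: diploid genotype and its gamete call matrix.

    Returns (diploid row, gametes (nuclei x markers) int8, truth for this
    individual only). Error flips and missingness are applied to every
    assayed marker; failed nuclei get the elevated missing rate.
    """
    lam = cfg.lambda_cc if lam is None else lam
    tab = marker_map.table
    n_markers = len(tab)
    chrom_index = {c: np.flatnonzero((tab["chromosome"] == c).to_numpy()) for c in marker_map.chromosomes}
    rel = tab["rel_position"].to_numpy()

    het = rng.random(n_markers) < cfg.heterozygosity
    hap1 = rng.integers(0, 2, size=n_markers).astype(np.int8)
    hap2 = np.where(het, 1 - hap1, hap1).astype(np.int8)
    diploid = np.where(het, HET, hap1).astype(np.int8)

    truth = SimTruth()
    truth.hap1[individual_id] = hap1
    truth.het_mask[individual_id] = het
    truth.lambda_by_individual[individual_id] = lam

    n_nuc = cfg.nuclei_per_individual
    gametes = np.empty((n_nuc, n_markers), dtype=np.int8)
    for g in range(n_nuc):
        nuc = f"{individual_id}_n{g + 1}"
        truth.crossovers[nuc] = {}
        truth.start_hap[nuc] = {}
        alleles = np.empty(n_markers, dtype=np.int8)
        per_chrom = sample_crossover_positions(
            rng, lam, cfg.interference_nu, len(chrom_index), obligate=cfg.obligate_co
        )
        for (chrom, idx), pos in zip(chrom_index.items(), per_chrom):
            h0 = int(rng.integers(0, 2))
            truth.crossovers[nuc][chrom] = pos
            truth.start_hap[nuc][chrom] = h0
            origin = (h0 + np.searchsorted(pos, rel[idx])) % 2
            alleles[idx] = np.where(origin == 0, hap1[idx], hap2[idx])
        err = rng.random(n_markers) < cfg.error_rate
        failed = rng.random() < cfg.nucleus_failure_rate
        miss_rate = cfg.failed_missing_rate if failed else cfg.missing_rate
        miss = rng.random(n_markers) < miss_rate
        if failed:
            truth.failed_nuclei.add(nuc)
        truth.error_mask[nuc] = err
        truth.missing_mask[nuc] = miss
        calls = np.where(err, 1 - alleles, alleles)
        calls = np.where(miss, MISSING, calls).astype(np.int8)
        gametes[g] = calls
    return diploid, gametes, truth


def _merge_truth(total: SimTruth, part: SimTruth) -> None:
    for name in ("hap1", "het_mask", "crossovers", "start_hap", "error_mask",
                 "missing_mask", "lambda_by_individual"):
        getattr(total, name).update(getattr(part, name))
    total.failed_nuclei |= part.failed_nuclei


def simulate_cohort(cfg: SimConfig, rng: np.random.Generator | None = None) -> Cohort:
    """Simulate the full two-subpopulation, two-treatment study bundle."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    marker_map = _simulate_marker_map(cfg, rng)

    n = cfg.n_individuals
    n_div = int(round(n * cfg.diversity_fraction))
    ids = [f"ind{i + 1:04d}" for i in range(n)]
    subpop = ["diversity_panel"] * n_div + ["population_variety"] * (n - n_div)
    treatment = [("control" if i % 2 == 0 else "nutrient_deficiency") for i in range(n)]
    meta = pd.DataFrame({"individual_id": ids, "subpopulation": subpop, "treatment": treatment})

    indicators = None
    extra = np.zeros(n)
    if cfg.n_effect_alleles > 0:
        freqs = np.linspace(0.5, 0.1, cfg.n_effect_alleles)
        mat = (rng.random((n, cfg.n_effect_alleles)) < freqs[None, :]).astype(int)
        indicators = pd.DataFrame(
            mat, index=ids, columns=[f"allele{j + 1}" for j in range(cfg.n_effect_alleles)]
        )
        extra = mat.sum(axis=1) * cfg.allele_effect

    truth = SimTruth()
    diploid_rows = np.empty((n, cfg.n_markers_per_chrom * cfg.n_chromosomes), dtype=np.int8)
    gam_blocks, nuclei_ids, nuclei_of = [], [], {}
    for i, ind in enumerate(ids):
        lam = cfg.lambda_cc + extra[i]
        if treatment[i] == "nutrient_deficiency":
            lam *= 1.0 - cfg.nd_effect_delta
        dip, gam, part = simulate_meiosis(cfg, rng, marker_map, ind, lam=lam)
        _merge_truth(truth, part)
        diploid_rows[i] = dip
        gam_blocks.append(gam)
        nuc = [f"{ind}_n{g + 1}" for g in range(cfg.nuclei_per_individual)]
        nuclei_ids.extend(nuc)
        nuclei_of[ind] = nuc

    marker_ids = list(marker_map.marker_ids)
    gametes = GenotypeMatrix(nuclei_ids, marker_ids, np.vstack(gam_blocks), "haploid")
    diploid = GenotypeMatrix(ids, marker_ids, diploid_rows, "diploid")
    return Cohort(
        config=cfg,
        marker_map=marker_map,
        gametes=gametes,
        diploid=diploid,
        meta=meta,
        nuclei_of=nuclei_of,
        truth=truth,
        allele_indicators=indicators,
    )


def phasing_accuracy(cohort: Cohort, parents: dict) -> float:
    """Fraction of phased markers matching the true haplotype, up to flip.

    For each phased chromosome the inferred haplotype-A alleles are compared
    with the simulated haplotype-1 alleles at the same markers; since the A/B
    labelling is arbitrary, agreement is taken as the better of the two
    per-chromosome orientations. Marker-weighted over all chromosomes and
    individuals.
    """
    tab = cohort.marker_map.table
    col_of = {m: j for j, m in enumerate(tab["marker_id"])}
    matched = total = 0
    for ind, parent in parents.items():
        hap1 = cohort.truth.hap1[ind]
        for pc in parent.chromosomes.values():
            cols = np.asarray([col_of[m] for m in pc.marker_ids])
            agree = int((pc.hap_a == hap1[cols]).sum())
            matched += max(agree, len(cols) - agree)
            total += len(cols)
    return matched / total if total else float("nan")


def phase_identifiable(cohort: Cohort) -> pd.DataFrame:
    """Flag (individual, chromosome) cells whose phase is identifiable.

    When at least half of an individual's gametes carry an odd number of
    crossovers inside the same inter-marker interval, the two phase
    orientations of the flanking chromosome arms explain the gamete calls
    with equal total agreement (the crossovers simply move to the
    complementary gametes), so no gamete-based phasing can distinguish them.
    Such cells are detectability-censored for exact-recovery comparisons.
    """
    tab = cohort.marker_map.table
    rel_all = tab["rel_position"].to_numpy()
    chrom_cols = {
        c: np.flatnonzero((tab["chromosome"] == c).to_numpy())
        for c in cohort.marker_map.chromosomes
    }
    rows = []
    for ind, nuclei in cohort.nuclei_of.items():
        het = cohort.truth.het_mask[ind]
        for chrom, cols in chrom_cols.items():
            rel = rel_all[cols[het[cols]]]
            m = len(rel)
            n_odd = np.zeros(m + 1, dtype=int)
            for nuc in nuclei:
                pos = cohort.truth.crossovers[nuc][chrom]
                bins = np.searchsorted(rel, pos)
                n_odd += np.bincount(bins, minlength=m + 1) % 2
            internal = n_odd[1:m] if m >= 2 else np.zeros(0, dtype=int)
            ambiguous = bool((2 * internal >= len(nuclei)).any())
            rows.append(
                {"individual_id": ind, "chromosome": chrom, "identifiable": not ambiguous}
            )
    return pd.DataFrame(rows)


def expected_detectable_events(
    cohort: Cohort, cfg: CrossoverConfig | None = None
) -> pd.DataFrame:
    """Events the calling rules can detect, derived from the simulated truth.

    For each nucleus and chromosome the true haplotype origin of every
    informative marker follows from the recorded crossover positions (no
    error or missingness is applied); window labels are the per-window marker
    majority and label changes are filtered by the gap rule. This bypasses
    phasing and origin labelling entirely, so it is an independent yardstick
    for the zero-noise pipeline: crossovers beyond the outermost informative
    window midpoints and double crossovers within one window are censored
    here exactly as they are unobservable in the data.
    """
    cfg = cfg or CrossoverConfig()
    wf = cfg.window_fraction
    n_win = cfg.n_windows
    tab = cohort.marker_map.table
    rel_all = tab["rel_position"].to_numpy()
    chrom_cols = {
        c: np.flatnonzero((tab["chromosome"] == c).to_numpy()) for c in cohort.marker_map.chromosomes
    }
    rows = []
    for ind, nuclei in cohort.nuclei_of.items():
        het = cohort.truth.het_mask[ind]
        for nuc in nuclei:
            for chrom, cols in chrom_cols.items():
                inf_cols = cols[het[cols]]
                rel = rel_all[inf_cols]
                pos = cohort.truth.crossovers[nuc][chrom]
                h0 = cohort.truth.start_hap[nuc][chrom]
                origin = (h0 + np.searchsorted(pos, rel)) % 2
                labels = []
                for w in range(n_win):
                    upper = rel <= 1.0 if w == n_win - 1 else rel < (w + 1) * wf
                    in_w = origin[(rel >= w * wf) & upper]
                    if len(in_w) == 0:
                        labels.append(-1)
                        continue
                    ones = int(in_w.sum())
                    zeros = len(in_w) - ones
                    labels.append(0 if zeros > ones else (1 if ones > zeros else -1))
                informative = [w for w in range(n_win) if labels[w] >= 0]
                for a, b in zip(informative[:-1], informative[1:]):
                    if labels[a] == labels[b]:
                        continue
                    sep = (b - a) * wf
                    ok = sep <= cfg.max_gap_rel + 1e-9 if cfg.inclusive_gap else sep < cfg.max_gap_rel - 1e-9
                    if ok:
                        rows.append(
                            {
                                "individual_id": ind,
                                "nucleus_id": nuc,
                                "chromosome": chrom,
                                "position_rel": (a + b + 1) * wf / 2.0,
                            }
                        )
    return pd.DataFrame(rows, columns=["individual_id", "nucleus_id", "chromosome", "position_rel"])
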