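"""Synthetic NIPT cohorts with known ground truth.

The generator emulates the data model the pipeline consumes, at the level
where its assumptions live:

* Per-bin read counts are Poisson draws around a length-proportional
  expectation, so log2 ratios carry the Gaussian-limit noise that binomial
  read counting induces at 100-kb resolution.
* A fixed latent *fetal signature* ``s`` (zero-mean, per-generator) perturbs
  autosomal bin dosages by ``ff * s_i`` — the minimal embodiment of the
  premise that fetal and maternal fragments are non-uniformly distributed,
  so local read depth is predictive of FF.
* chrX dosage follows the karyotype: 1 for XX, ``1 - ff/2`` for XY (and
  X0/XYY), ``1 + ff/2`` for XXX, 1 for XXY; twins subtract ``ff_c/2`` per
  male fetus.
* chrY 5-kb bins split into *informative* bins whose counts scale with the
  male fetal signal (with per-bin "male specificity" weights) and
  uninformative bins carrying heavy-tailed, FF-unrelated background — the
  structure the FFY lasso is meant to exploit.
* Optional events: trisomies 13/18/21 (+ff/2 dosage on the chromosome),
  sex aneuploidies, twins (component FFs summing to the total), and
  FF-independent maternal CNVs on chrX or autosomes.

Everything is deterministic under the seed.  The default toy genome
(~3,000 autosomal bins) keeps tests fast; any custom grid is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .grids import BinGrid, make_bin_grid
from .profiles import CohortManifest, CopyNumberProfile, ManifestRecord

KARYOTYPE_X_SHIFT = {  # chrX dosage offset in units of ff/2, relative to XX
    "XX": 0.0, "XY": -1.0, "X": -1.0, "XXX": 1.0, "XXY": 0.0, "XYY": -1.0,
}
KARYOTYPE_Y_COPIES = {"XX": 0, "XY": 1, "X": 0, "XXX": 0, "XXY": 1, "XYY": 2}
KARYOTYPE_SEX = {"XX": "female", "XY": "male", "X": "female", "XXX": "female",
                 "XXY": "male", "XYY": "male"}


def toy_grid(resolution: int = 100_000) -> BinGrid:
    """Small 22-autosome + X + Y grid (~3,000 autosomal bins) for fast runs."""
    lengths = {str(c): (160 - 2 * c) * resolution for c in range(1, 23)}
    lengths["X"] = 150 * resolution
    lengths["Y"] = 50 * resolution
    return make_bin_grid(lengths, resolution, assembly_label="toy")


def toy_y_grid(resolution: int = 5_000) -> BinGrid:
    """200-bin 5-kb chrY grid matching the toy genome."""
    return make_bin_grid({"Y": 200 * resolution}, resolution, assembly_label="toy")


@dataclass
class SimulationParams:
    """Stated world of the generator; defaults are the tested conditions."""

    n_samples: int = 800
    male_fraction: float = 0.5
    ff_low: float = 0.02
    ff_high: float = 0.25
    reads_per_sample_mean: float = 3e6
    reads_per_sample_sd: float = 3e5
    grid: BinGrid | None = None
    y_grid: BinGrid | None = None
    fetal_signature_scale: float = 0.05
    informative_y_fraction: float = 0.3
    y_informative_unit: float = 8e-5
    y_background_level: float = 5e-7
    y_heavy_tail_sigma: float = 0.8
    trisomy_rates: dict[str, float] = field(
        default_factory=lambda: {"13": 0.002, "18": 0.003, "21": 0.006})
    sex_aneuploidy_counts: dict[str, int] = field(default_factory=dict)
    twin_fraction: float = 0.0
    twin_composition: dict[str, float] = field(
        default_factory=lambda: {"MM": 0.3, "MF": 0.4, "FF": 0.3})
    twin_split: str = "equal"  # or "random": per-fetus share U(0.3, 0.7)
    maternal_cnv_rate: float = 0.01
    maternal_x_weight: float = 0.5
    missing_rate: float = 0.01
    seed: int = 0
    world_seed: int | None = None  # latent structure seed; defaults to `seed`

    def validate(self) -> None:
        probs = [self.male_fraction, self.twin_fraction, self.missing_rate,
                 self.maternal_cnv_rate, self.maternal_x_weight,
                 self.informative_y_fraction, *self.trisomy_rates.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("all rates/fractions must lie in [0, 1]")
        if not (0.0 <= self.ff_low <= self.ff_high < 1.0):
            raise ConfigurationError("need 0 <= ff_low <= ff_high < 1")
        if self.reads_per_sample_mean <= 0:
            raise ConfigurationError("reads_per_sample_mean must be positive")
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if abs(sum(self.twin_composition.values()) - 1.0) > 1e-9:
            raise ConfigurationError("twin composition probabilities must sum to 1")
        if self.twin_split not in {"equal", "random"}:
            raise ConfigurationError(f"unknown twin_split {self.twin_split!r}")
        for kt in self.sex_aneuploidy_counts:
            if kt not in KARYOTYPE_X_SHIFT or kt in {"XX", "XY"}:
                raise ConfigurationError(f"unknown sex-aneuploidy karyotype {kt!r}")
        if sum(self.sex_aneuploidy_counts.values()) > self.n_samples:
            raise ConfigurationError("more sex aneuploidies requested than samples")


@dataclass
class SimulatedSample:
    sample_id: str
    profile: CopyNumberProfile
    true_ff: float
    karyotypes: list[str]  # one per fetus
    fetus_ffs: list[float]
    male_ff: float  # summed FF of Y-bearing fetuses
    trisomies: list[str]
    maternal_cnv: str  # "" or "chrom:start_bin-end_bin:shift"


@dataclass
class SimulatedCohort:
    samples: list[SimulatedSample]
    params: SimulationParams
    signature: np.ndarray  # latent fetal signature on autosomal grid bins

    @property
    def profiles(self) -> list[CopyNumberProfile]:
        return [s.profile for s in self.samples]

    @property
    def truth(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            rows.append({
                "sample_id": s.sample_id,
                "true_ff": s.true_ff,
                "sex": s.profile.sex_label,
                "karyotype": "/".join(s.karyotypes),
                "n_fetuses": len(s.karyotypes),
                "male_ff": s.male_ff,
                "trisomies": ",".join(s.trisomies),
                "maternal_cnv": s.maternal_cnv,
            })
        return pd.DataFrame(rows)

    def manifest(self, profile_paths: dict[str, str] | None = None,
                 y_paths: dict[str, str] | None = None) -> CohortManifest:
        recs = []
        for s in self.samples:
            recs.append(ManifestRecord(
                sample_id=s.sample_id,
                path=(profile_paths or {}).get(s.sample_id, ""),
                sex=s.profile.sex_label,
                y_path=(y_paths or {}).get(s.sample_id),
            ))
        return CohortManifest(recs)


class CohortGenerator:
    """Holds the per-world latent structure (signature, Y-bin roles).

    The latent structure is seeded by ``params.world_seed`` (falling back to
    ``params.seed``), so cohorts drawn with different sampling seeds but the
    same world share one fetal signature and one set of informative Y bins —
    a model trained on one such cohort transfers to the others.
    """

    def __init__(self, params: SimulationParams):
        params.validate()
        self.params = params
        self.grid = params.grid or toy_grid()
        self.y_grid = params.y_grid or toy_y_grid()
        world = params.world_seed if params.world_seed is not None else params.seed
        rng = np.random.default_rng(world)
        self._chrom_masks = {
            "auto": ~self.grid.chrom_mask({"X", "Y"}),
            "X": self.grid.chrom_mask({"X"}),
            "Y": self.grid.chrom_mask({"Y"}),
        }
        n_auto = int(self._chrom_masks["auto"].sum())
        sig = rng.standard_normal(n_auto)
        sig -= sig.mean()
        self.signature = sig * params.fetal_signature_scale
        n_y = self.y_grid.n_bins
        n_inf = int(round(params.informative_y_fraction * n_y))
        inf_idx = rng.choice(n_y, size=n_inf, replace=False)
        self.y_informative = np.zeros(n_y, dtype=bool)
        self.y_informative[inf_idx] = True
        # per-bin "male specificity" of informative windows
        self.y_weights = np.zeros(n_y)
        self.y_weights[self.y_informative] = rng.uniform(0.5, 1.5, size=n_inf)
        lengths = np.array([e - s for _, s, e in self.grid.bins], dtype=float)
        self._bin_share = lengths / lengths.sum()
        self._rng = np.random.default_rng(params.seed)

    # -- low-level draws ---------------------------------------------------

    def _total_reads(self, rng) -> float:
        p = self.params
        return float(max(1e5, rng.normal(p.reads_per_sample_mean,
                                         p.reads_per_sample_sd)))

    def draw_y_counts(self, rng, total_reads: float, y_signal: float) -> np.ndarray:
        """Normalized 5-kb chrY counts for a sample.

        ``y_signal`` is sum over fetuses of ff * chrY copy number (1 for a
        pure male liquid biopsy).
        """
        p = self.params
        mu = np.where(
            self.y_informative,
            p.y_background_level + y_signal * p.y_informative_unit * self.y_weights,
            p.y_background_level
            * np.exp(rng.normal(0.0, p.y_heavy_tail_sigma, self.y_grid.n_bins)),
        )
        reads = rng.poisson(mu * total_reads)
        return reads / total_reads

    # -- one sample --------------------------------------------------------

    def _draw_fetuses(self, rng, forced_karyotype: str | None):
        p = self.params
        ff = float(rng.uniform(p.ff_low, p.ff_high))
        if forced_karyotype is not None:
            return ff, [forced_karyotype], [ff]
        if rng.uniform() < p.twin_fraction:
            kinds = list(p.twin_composition)
            probs = np.array([p.twin_composition[k] for k in kinds])
            comp = kinds[int(rng.choice(len(kinds), p=probs))]
            karyos = {"MM": ["XY", "XY"], "MF": ["XY", "XX"],
                      "FF": ["XX", "XX"]}[comp]
            share = 0.5 if p.twin_split == "equal" else float(rng.uniform(0.3, 0.7))
            return ff, karyos, [ff * share, ff * (1 - share)]
        karyo = "XY" if rng.uniform() < p.male_fraction else "XX"
        return ff, [karyo], [ff]

    def simulate_sample(self, sample_id: str, rng,
                        forced_karyotype: str | None = None) -> SimulatedSample:
        p = self.params
        ff, karyos, ffs = self._draw_fetuses(rng, forced_karyotype)
        total = self._total_reads(rng)
        dosage = np.ones(self.grid.n_bins)
        auto = self._chrom_masks["auto"]
        dosage[auto] += ff * self.signature
        trisomies = []
        for chrom, rate in p.trisomy_rates.items():
            if rng.uniform() < rate:
                trisomies.append(chrom)
                dosage[self.grid.chrom_mask({chrom})] += ff / 2.0
        x_shift = sum(
            f * KARYOTYPE_X_SHIFT[k] / 2.0 for k, f in zip(karyos, ffs)
        )
        dosage[self._chrom_masks["X"]] += x_shift
        male_ff = sum(f * KARYOTYPE_Y_COPIES[k] for k, f in zip(karyos, ffs))
        dosage[self._chrom_masks["Y"]] = 0.01 + male_ff / 2.0
        maternal_cnv = ""
        if rng.uniform() < p.maternal_cnv_rate:
            chrom = ("X" if rng.uniform() < p.maternal_x_weight
                     else str(int(rng.integers(1, 23))))
            cmask = np.flatnonzero(self.grid.chrom_mask({chrom}))
            seg_len = int(rng.integers(10, min(51, cmask.size)))
            start = int(rng.integers(0, cmask.size - seg_len + 1))
            shift = 0.5 * (1 if rng.uniform() < 0.5 else -1)
            seg = cmask[start:start + seg_len]
            dosage[seg] = np.maximum(dosage[seg] + shift, 0.0)
            maternal_cnv = f"{chrom}:{start}-{start + seg_len}:{shift:+.1f}"
        lam = total * self._bin_share
        reads = rng.poisson(np.maximum(dosage, 0.0) * lam)
        with np.errstate(divide="ignore"):
            log2 = np.where(reads > 0, np.log2(np.maximum(reads, 1) / lam), np.nan)
        if p.missing_rate > 0:
            log2[rng.uniform(size=log2.size) < p.missing_rate] = np.nan
        sex = ("unknown" if len(set(KARYOTYPE_SEX[k] for k in karyos)) > 1
               else KARYOTYPE_SEX[karyos[0]])
        y_counts = self.draw_y_counts(rng, total, male_ff)
        profile = CopyNumberProfile(sample_id, self.grid, log2, sex_label=sex,
                                    y_counts=y_counts, y_grid=self.y_grid)
        return SimulatedSample(sample_id, profile, ff, karyos, ffs, male_ff,
                               trisomies, maternal_cnv)


def simulate_cohort(params: SimulationParams | None = None) -> SimulatedCohort:
    """Generate a full cohort under the stated parameters (seed-deterministic)."""
    params = params or SimulationParams()
    gen = CohortGenerator(params)
    rng = gen._rng
    forced: list[str | None] = [None] * params.n_samples
    slot = 0
    for karyo, count in sorted(params.sex_aneuploidy_counts.items()):
        for _ in range(count):
            forced[slot] = karyo
            slot += 1
    rng.shuffle(forced)
    width = len(str(params.n_samples))
    samples = [
        gen.simulate_sample(f"S{i:0{width}d}", rng, forced_karyotype=forced[i])
        for i in range(params.n_samples)
    ]
    return SimulatedCohort(samples, params, gen.signature)


def simulate_reference_sets(
    params: SimulationParams | None = None,
    n_lb_males: int = 20,
    n_females: int = 50,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean chrY abundances for the FFY reference anchors.

    Liquid-biopsy males are simulated at FF = 1 (pure male genome, one chrY
    copy); the female set carries background only.  Returns the two arrays of
    per-sample mean abundances (feed to :func:`fetalfrac.ffy.build_reference`).
    """
    params = params or SimulationParams()
    gen = CohortGenerator(params)
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    lb = np.array([
        gen.draw_y_counts(rng, gen._total_reads(rng), 1.0).mean()
        for _ in range(n_lb_males)
    ])
    fem = np.array([
        gen.draw_y_counts(rng, gen._total_reads(rng), 0.0).mean()
        for _ in range(n_females)
    ])
    return lb, fem
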