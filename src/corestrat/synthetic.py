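"""Synthetic sediment-core generator with known ground truth.

Emulates the data structure of a short (~37 cm) tropical-lake gravity
core spanning roughly 1850-2018 CE with every record the downstream
pipeline consumes:

* total 210Pb activities decaying exponentially over a supported
  baseline, with multiplicative measurement noise and 1-sigma errors;
* a pigment table over the standard taxonomically diagnostic pigments,
  lognormal around a stable baseline before a planted eutrophication
  onset (default 1920 CE) and ``fold_change`` times higher after it,
  the rise either a step or a linear ramp a few samples wide;
* cladoceran body-part counts (Poisson) whose underlying abundance drops
  by ``cladoceran_decline_frac`` after a planted collapse year (default
  1957), plus rare Chaoborus mandibles with no planted change;
* Lycopodium marker-spore tallies, Normal(9666, 671) added spores per
  subsample (truncated at 1) with a binomial counted fraction;
* reflectance spectra whose 655-680 nm absorption trough deepens in
  proportion to the summed pigment concentration;
* bulk geochemistry (TC%, TN%, d13C with an atmospheric Suess trend
  imprinted, d15N).

Every draw comes from one seeded generator in a fixed order, so a fixed
seed reproduces the dataset byte for byte.  The planted parameters are
returned as a :class:`SyntheticTruth` for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geochem import default_suess_curve
from .geochron import PB210_LAMBDA, ActivityProfile
from .pigments import PIGMENT_VOCABULARY, CYANO_PIGMENTS
from .spectral import SpectralCube

__all__ = ["SyntheticConfig", "SyntheticTruth", "CoreTable",
           "generate_core", "truth_report", "PIGMENT_BASELINES",
           "CLADOCERAN_BASELINES"]

#: Baseline pigment concentrations (nmol / g OC) before the planted
#: eutrophication onset; order follows the pigment vocabulary.
PIGMENT_BASELINES: dict[str, float] = {
    "bb_carotene": 30.0, "chlorophyll_a": 12.0, "pheophytin_a": 60.0,
    "pheophorbide_a": 45.0, "alloxanthin": 8.0, "diatoxanthin": 25.0,
    "diadinoxanthin": 15.0, "dinoxanthin": 5.0, "peridinin": 4.0,
    "lutein": 20.0, "echinenone": 10.0, "canthaxanthin": 12.0,
    "myxoxanthophyll": 6.0, "oscillaxanthin": 3.0, "zeaxanthin": 9.0,
}

#: Pre-collapse mean individuals per subsample, per taxon.  Chaoborus is
#: deliberately rare and carries no planted decline (its larvae are
#: under-sampled by cladoceran-targeted counting).
CLADOCERAN_BASELINES: dict[str, float] = {
    "Alona": 60.0, "Chydorus": 40.0, "Bosmina": 30.0,
}
CHAOBORUS_MEAN = 0.5

#: Body parts generated per taxon with their per-individual multiplicity.
_TAXON_PARTS: dict[str, tuple[tuple[str, int], ...]] = {
    "Alona": (("headshield", 1), ("carapace", 2)),
    "Chydorus": (("headshield", 1), ("carapace", 2)),
    "Bosmina": (("headshield", 1), ("carapace", 2)),
    "Chaoborus": (("mandible", 2),),
}


@dataclass
class SyntheticConfig:
    """Planted study conditions for one synthetic core."""

    seed: int = 0
    core_length_cm: float = 37.0
    sample_thickness_cm: float = 1.0
    surface_year: float = 2018.0
    sedimentation_rate_cm_per_yr: float = 0.21
    dry_bulk_density_g_cm3: float = 0.5
    pb210_flux: float = 500.0           # unsupported surface activity, Bq/kg
    supported_pb210: float = 30.0
    activity_cv: float = 0.10
    intervention_year: float = 1920.0
    collapse_year: float = 1957.0
    pigment_fold_change: float = 5.0    # within the observed 2-10x range
    cladoceran_decline_frac: float = 0.75  # within the observed 60-85%
    spore_mean: float = 9666.0
    spore_sd: float = 671.0
    spectra_noise_sd: float = 0.002
    pigment_noise_sd: float = 0.15      # sd of multiplicative log-noise
    pigment_ar1: float = 0.0            # AR(1) coefficient of the log-noise
    transition_width_samples: int = 3
    ramp: bool = True                   # linear ramp (False = step rise)
    cyano_second_rise: bool = False     # extra late cyanobacterial rise
    cyano_rise_year: float = 1990.0
    cyano_fold_change: float = 3.0
    sample_volume_cm3: float = 2.0
    spore_count_fraction: float = 0.35  # expected fraction of spores found

    def __post_init__(self) -> None:
        for name in ("core_length_cm", "sample_thickness_cm",
                     "sedimentation_rate_cm_per_yr",
                     "dry_bulk_density_g_cm3", "pb210_flux",
                     "sample_volume_cm3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.cladoceran_decline_frac < 1:
            raise ValueError("cladoceran_decline_frac must be in (0, 1)")
        if self.intervention_year >= self.surface_year:
            raise ValueError("intervention_year must precede surface_year")
        if self.intervention_year <= self.basal_year:
            raise ValueError("intervention year outside core span")
        if self.collapse_year >= self.surface_year or \
                self.collapse_year <= self.basal_year:
            raise ValueError("collapse year outside core span")
        if self.activity_cv < 0 or self.spectra_noise_sd < 0 or \
                self.pigment_noise_sd < 0:
            raise ValueError("noise levels must be >= 0")

    @property
    def basal_year(self) -> float:
        """True age of the deepest sample mid-depth."""
        deepest_mid = self.core_length_cm - 0.5 * self.sample_thickness_cm
        return self.surface_year - deepest_mid / self.sedimentation_rate_cm_per_yr

    def depth_of_year(self, year: float) -> float:
        return (self.surface_year - year) * self.sedimentation_rate_cm_per_yr


@dataclass
class SyntheticTruth:
    """Planted ground truth for parameter-recovery tests."""

    depth_mid: np.ndarray
    true_age: np.ndarray
    true_intervention_depth: float
    true_collapse_depth: float
    pre_post_means: dict[str, tuple[float, float]]
    config: SyntheticConfig

    def __post_init__(self) -> None:
        if np.any(np.diff(self.true_age) >= 0):
            raise AssertionError("true ages must strictly decrease downcore")


@dataclass
class CoreTable:
    """Bundle of depth-indexed records for one (synthetic) core."""

    activity: ActivityProfile
    pigments: pd.DataFrame        # wide, index depth_cm, nmol/g OC
    counts: pd.DataFrame          # long subfossil schema
    geochem: pd.DataFrame
    seed: int | None = None

    def write_csvs(self, outdir) -> dict[str, str]:
        """Write the standard CSV set; each file opens with a comment
        line recording the generator seed."""
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = f"# corestrat synthetic seed={self.seed}\n"
        paths = {}

        def _write(name, df, index=False):
            p = outdir / name
            with open(p, "w") as fh:
                fh.write(header)
                df.to_csv(fh, index=index)
            paths[name] = str(p)

        _write("activity.csv", self.activity.to_frame())
        pig_long = (self.pigments.reset_index()
                    .melt(id_vars="depth_cm", var_name="pigment",
                          value_name="conc"))
        pig_long["units"] = "nmol_g_oc"
        _write("pigments.csv", pig_long.sort_values(
            ["depth_cm", "pigment"]).reset_index(drop=True))
        _write("counts.csv", self.counts)
        _write("geochem.csv", self.geochem)
        return paths


def _effect_fraction(ages: np.ndarray, onset_year: float, ramp_years: float,
                     ramp: bool) -> np.ndarray:
    """0 before the onset, 1 after it (after the ramp when ramp=True)."""
    if not ramp or ramp_years <= 0:
        return (ages >= onset_year).astype(float)
    return np.clip((ages - onset_year) / ramp_years, 0.0, 1.0)


def generate_core(config: SyntheticConfig
                  ) -> tuple[CoreTable, SpectralCube, SyntheticTruth]:
    """Generate one complete synthetic core dataset.

    Returns the tabular records, the reflectance cube, and the planted
    truth.  All randomness derives from ``config.seed``; the same config
    yields identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lam = PB210_LAMBDA
    s = cfg.sedimentation_rate_cm_per_yr

    n = int(round(cfg.core_length_cm / cfg.sample_thickness_cm))
    tops = np.arange(n) * cfg.sample_thickness_cm
    bots = tops + cfg.sample_thickness_cm
    mids = 0.5 * (tops + bots)
    ages = cfg.surface_year - mids / s          # true age at mid-depth
    elapsed = mids / s

    # --- 210Pb / 137Cs activities ------------------------------------
    cu_true = cfg.pb210_flux * np.exp(-lam * elapsed)
    eps = rng.normal(0.0, 1.0, n) * cfg.activity_cv
    total = cfg.supported_pb210 + cu_true * (1.0 + eps)
    total_err = cfg.activity_cv * cu_true
    cs_true = 2.0 * np.exp(-0.5 * ((ages - 1963.0) / 8.0) ** 2)
    cs = np.maximum(cs_true + rng.normal(0.0, 0.1, n), 0.0)
    activity = ActivityProfile(
        depth_top=tops, depth_bottom=bots,
        dry_mass_cum=cfg.dry_bulk_density_g_cm3 * mids,
        total_pb210=total, total_pb210_err=total_err,
        cs137=cs, cs137_err=np.full(n, 0.3),
    )

    # --- pigments -----------------------------------------------------
    ramp_years = cfg.transition_width_samples * cfg.sample_thickness_cm / s
    frac = _effect_fraction(ages, cfg.intervention_year, ramp_years, cfg.ramp)
    cy_frac = _effect_fraction(ages, cfg.cyano_rise_year, ramp_years,
                               cfg.ramp) if cfg.cyano_second_rise else None
    sigma = cfg.pigment_noise_sd
    phi = cfg.pigment_ar1
    pig = {}
    truth_means: dict[str, tuple[float, float]] = {}
    for name, base in PIGMENT_BASELINES.items():
        mean = base * (1.0 + (cfg.pigment_fold_change - 1.0) * frac)
        if cy_frac is not None and name in CYANO_PIGMENTS:
            mean = mean * (1.0 + (cfg.cyano_fold_change - 1.0) * cy_frac)
        e = rng.normal(0.0, 1.0, n)
        if phi:
            for i in range(1, n):
                e[i] = phi * e[i - 1] + np.sqrt(1 - phi ** 2) * e[i]
        # mean-preserving lognormal noise: E[exp(sigma*e - sigma^2/2)] = 1
        pig[name] = mean * np.exp(sigma * e - 0.5 * sigma ** 2)
        truth_means[f"pigment:{name}"] = (
            base, base * cfg.pigment_fold_change)
    pigments = pd.DataFrame(pig, index=pd.Index(mids, name="depth_cm"))

    # --- reflectance spectra ------------------------------------------
    wl = np.arange(590.0, 731.0)
    pigsum = pigments.sum(axis=1).to_numpy()
    trough_depth = 0.35 * pigsum / pigsum.max()
    shape = np.exp(-0.5 * ((wl - 667.0) / 6.0) ** 2)
    refl = 0.5 - trough_depth[:, None] * shape[None, :]
    refl = refl + rng.normal(0.0, cfg.spectra_noise_sd, refl.shape)
    cube = SpectralCube(depth=mids, wavelength=wl,
                        reflectance=np.clip(refl, 1e-6, None))

    # --- subfossil counts ---------------------------------------------
    post_collapse = ages >= cfg.collapse_year
    rows = []
    spores_added = np.maximum(
        np.rint(rng.normal(cfg.spore_mean, cfg.spore_sd, n)), 1.0
    ).astype(int)
    spores_counted = rng.binomial(spores_added, cfg.spore_count_fraction)
    for taxon, parts in _TAXON_PARTS.items():
        if taxon == "Chaoborus":
            mean_ind = np.full(n, CHAOBORUS_MEAN)
        else:
            base = CLADOCERAN_BASELINES[taxon]
            mean_ind = np.where(post_collapse,
                                base * (1.0 - cfg.cladoceran_decline_frac),
                                base)
            truth_means[f"cladoceran:{taxon}"] = (
                base, base * (1.0 - cfg.cladoceran_decline_frac))
        for part, mult in parts:
            counts = rng.poisson(mean_ind * mult)
            for i in range(n):
                rows.append({
                    "depth_cm": mids[i], "taxon": taxon, "body_part": part,
                    "count": int(counts[i]),
                    "sample_volume_cm3": cfg.sample_volume_cm3,
                    "spores_counted": int(spores_counted[i]),
                    "spores_added": int(spores_added[i]),
                })
    counts = pd.DataFrame(rows)

    # --- bulk geochemistry --------------------------------------------
    curve = default_suess_curve()
    tc = 4.0 + 2.5 * frac + rng.normal(0.0, 0.1, n)
    ratio = 11.0 - 1.6 * frac                       # atomic C:N target
    tn = (tc / 12.011) * 14.007 / ratio
    atm = np.array([curve(a) for a in ages])
    d13c = -25.5 + (atm - curve(1900.0)) + rng.normal(0.0, 0.1, n)
    d15n = 0.8 + rng.normal(0.0, 0.1, n)
    geochem = pd.DataFrame({
        "depth_cm": mids, "tc_pct": tc, "tn_pct": tn,
        "d13c_permil": d13c, "d15n_permil": d15n,
    })

    truth = SyntheticTruth(
        depth_mid=mids, true_age=ages,
        true_intervention_depth=cfg.depth_of_year(cfg.intervention_year),
        true_collapse_depth=cfg.depth_of_year(cfg.collapse_year),
        pre_post_means=truth_means, config=cfg,
    )
    table = CoreTable(activity=activity, pigments=pigments, counts=counts,
                      geochem=geochem, seed=cfg.seed)
    return table, cube, truth


def truth_report(truth: SyntheticTruth) -> pd.DataFrame:
    """Flat table of the planted parameters, for recovery comparisons."""
    cfg = truth.config
    rows = [
        ("intervention_year", cfg.intervention_year),
        ("intervention_depth_cm", truth.true_intervention_depth),
        ("collapse_year", cfg.collapse_year),
        ("collapse_depth_cm", truth.true_collapse_depth),
        ("pigment_fold_change", cfg.pigment_fold_change),
        ("cladoceran_decline_pct", 100.0 * cfg.cladoceran_decline_frac),
        ("sedimentation_rate_cm_yr", cfg.sedimentation_rate_cm_per_yr),
        ("mass_accum_rate_g_cm2_yr",
         cfg.sedimentation_rate_cm_per_yr * cfg.dry_bulk_density_g_cm3),
        ("surface_year", cfg.surface_year),
    ]
    for proxy, (pre, post) in truth.pre_post_means.items():
        rows.append((f"pre_mean[{proxy}]", pre))
        rows.append((f"post_mean[{proxy}]", post))
    return pd.DataFrame(rows, columns=["parameter", "value"])
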