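"""Synthetic multi-group microbiome study generator with planted effects.

Emulates the design of a polymicrobial periodontal-infection mouse study:
8 sequenced groups (healthy control, infection, three treatment-only
groups, and infection combined with each treatment) of 6 mice each,
bacterial and viral taxa with log-normal relative abundances, planted
multiplicative infection effects on a few viral species and one
health-associated bacterial species, graded treatment "recovery" toward
the control state, and an IL-6 level log-linearly coupled to a
disease-associated taxon.  Everything downstream of taxonomy annotation
(normalization, diversity, ordination, differential abundance, immune
correlation) can therefore be exercised against a known ground truth.

Count model: per-taxon log10 relative abundances are Gaussian around a
baseline plus the group's effect shift; the sample composition is their
softmax; reads are multinomial given a Poisson library size.  Treatment
recovery rho interpolates effects geometrically: an affected taxon's
abundance is multiplied by effect_fold^(1 - rho), so rho = 0 reproduces
the full infection effect and rho = 1 the control state.

Outputs are a pure function of (design, effects, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .immune import DEFAULT_MARKERS
from .tables import CountTable

#: the 8 sequenced study arms
DEFAULT_GROUPS = (
    "Control",
    "Infection",
    "Nisin",
    "L.lactis",
    "NonNisinL.lactis",
    "Infection+Nisin",
    "Infection+L.lactis",
    "Infection+NonNisinL.lactis",
)

#: the four co-inoculated periodontal pathogens
PATHOGENS = ("P_gingivalis", "T_denticola", "T_forsythia", "F_nucleatum")

_SPECIES_PER_GENUS = 4
_TRUTH_MC_DRAWS = 2000


@dataclass(frozen=True)
class StudyDesign:
    """Shape of the synthetic study.

    Defaults mirror the sequenced arm of the mouse model: 8 groups of 6
    animals, one oral sample per animal.  ``library_size_mean`` is the
    expected reads per sample (desk scale; RPM normalization makes depth
    a free parameter).
    """

    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_per_group: int = 6
    n_bacterial_taxa: int = 80
    n_viral_taxa: int = 40
    library_size_mean: float = 100_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ConfigError("need at least 2 groups")
        if len(set(self.groups)) != len(self.groups):
            raise ConfigError("group labels must be unique")
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be >= 2")
        if self.n_bacterial_taxa < 1 or self.n_viral_taxa < 1:
            raise ConfigError("taxa counts must be >= 1")
        if self.library_size_mean < 1000:
            raise ConfigError("library_size_mean must be >= 1000")

    def sample_ids(self) -> list[str]:
        return [f"{g}_{i}" for g in self.groups for i in range(1, self.n_per_group + 1)]


@dataclass(frozen=True)
class CytokineCoupling:
    """Log-linear link of one marker to one taxon's abundance.

    log10(marker + 0.1) = intercept + slope * log10(RPM_taxon + 0.1) + N(0, sigma).
    """

    taxon: str
    slope: float
    sigma: float
    intercept: float = 0.5


@dataclass(frozen=True)
class EffectSpec:
    """Planted effect structure.

    ``disease_taxa`` / ``health_taxa`` map taxon id to the multiplicative
    abundance effect under full infection (fold > 1 disease-associated,
    fold < 1 health-associated).  ``recovery`` maps group label to
    rho in [0, 1]; groups absent from the map sit at the control state
    (rho = 1).  ``lognormal_sigma`` is the per-taxon dispersion of log10
    relative abundance (a scalar, or a taxon -> sigma map).
    ``baseline_log10`` pins the baseline log10 weight of named taxa
    instead of drawing it, so a planted taxon's abundance tier (and hence
    its counting noise and whether it survives the ordination abundance
    cap) is part of the effect specification.
    """

    disease_taxa: dict = field(default_factory=dict)
    health_taxa: dict = field(default_factory=dict)
    recovery: dict = field(default_factory=dict)
    cytokine_coupling: dict = field(default_factory=dict)
    lognormal_sigma: float | dict = 0.3
    baseline_log10: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for taxon, fold in {**self.disease_taxa, **self.health_taxa}.items():
            if fold <= 0:
                raise ConfigError(f"effect_fold must be > 0 (taxon {taxon}: {fold})")
        for g, rho in self.recovery.items():
            if not 0.0 <= rho <= 1.0:
                raise ConfigError(f"recovery rho must be in [0, 1] (group {g}: {rho})")
        sigmas = (
            self.lognormal_sigma.values()
            if isinstance(self.lognormal_sigma, dict)
            else [self.lognormal_sigma]
        )
        if any(s < 0 for s in sigmas):
            raise ConfigError("lognormal_sigma must be >= 0")

    def sigma_for(self, taxon: str) -> float:
        if isinstance(self.lognormal_sigma, dict):
            return float(self.lognormal_sigma.get(taxon, 0.3))
        return float(self.lognormal_sigma)

    def fold_for(self, taxon: str) -> float:
        if taxon in self.disease_taxa:
            return float(self.disease_taxa[taxon])
        if taxon in self.health_taxa:
            return float(self.health_taxa[taxon])
        return 1.0


def default_recovery(groups=DEFAULT_GROUPS) -> dict[str, float]:
    """Recovery map matching the study arms' expected behaviour.

    Infection alone keeps the full effect (rho = 0); infection plus an
    effective treatment (nisin or the nisin-producing probiotic) recovers
    most of the way to control (rho = 0.9); infection plus the non-nisin
    probiotic recovers only partially (rho = 0.5); non-infected groups
    are at the control state.
    """
    rec = {}
    for g in groups:
        if g == "Infection":
            rec[g] = 0.0
        elif g.startswith("Infection+"):
            rec[g] = 0.5 if "NonNisin" in g else 0.9
    return rec


def default_effects(design: StudyDesign) -> EffectSpec:
    """Planted effects used throughout the packaged examples and tests.

    Two layers, mirroring what infection does to a real oral community:

    * focal taxa — three disease-associated viral species (folds 4, 3, 2
      under full infection) and one health-associated bacterial species
      (fold 0.25), pinned at a prominent baseline (about 1% of reads) so
      their differential abundance is measurable above counting noise;
      IL-6 is coupled to the strongest disease virus;
    * a broad dysbiosis signature — 16 moderate-abundance bacterial
      species (8 up x3, 8 down x3) whose baselines sit below the
      ordination abundance cap, so infection visibly shifts the
      Bray-Curtis geometry of the capped species table and treatment
      recovery moves it back toward control.
    """
    focal_folds = (4.0, 3.0, 2.0)
    disease = {
        f"vir_s{i + 1:03d}": f
        for i, f in enumerate(focal_folds[: design.n_viral_taxa])
    }
    health = {"bact_s001": 0.25}
    baselines = {t: 0.5 for t in (*disease, "bact_s001")}
    # dysbiosis signature on the last bacterial species (skipped in tiny designs)
    n_sig = 16 if design.n_bacterial_taxa >= 32 else 0
    sig = [
        f"bact_s{i:03d}"
        for i in range(design.n_bacterial_taxa - n_sig + 1, design.n_bacterial_taxa + 1)
    ]
    sig_up, sig_down = sig[: n_sig // 2], sig[n_sig // 2 :]
    for t, b in zip(sig, np.linspace(-1.5, -0.9, n_sig)):
        baselines[t] = float(b)
    disease.update({t: 3.0 for t in sig_up})
    health.update({t: 1.0 / 3.0 for t in sig_down})
    coupled = next(iter(disease))
    coupling = {"IL-6": CytokineCoupling(taxon=coupled, slope=1.0, sigma=0.3)}
    return EffectSpec(
        disease_taxa=disease,
        health_taxa=health,
        recovery=default_recovery(design.groups),
        cytokine_coupling=coupling,
        lognormal_sigma=0.3,
        baseline_log10=baselines,
    )


def _taxa_frame(design: StudyDesign) -> pd.DataFrame:
    rows = []
    for kingdom, prefix, n in (
        ("bacteria", "bact", design.n_bacterial_taxa),
        ("virus", "vir", design.n_viral_taxa),
    ):
        for i in range(1, n + 1):
            genus = f"{prefix}_g{(i - 1) // _SPECIES_PER_GENUS + 1:03d}"
            rows.append(
                {
                    "taxon_id": f"{prefix}_s{i:03d}",
                    "name": f"{kingdom} species {i}",
                    "level": "species",
                    "kingdom": kingdom,
                    "genus": genus,
                }
            )
    return pd.DataFrame(rows).set_index("taxon_id")


@dataclass
class StudyTruth:
    """Ground truth of one generated study.

    ``expected_log10_rpm`` is the exact expectation of a taxon's log10 RPM
    in each group under the generative model (the compositional
    normalizing constant is evaluated by seeded Monte Carlo, so the value
    is deterministic).  ``effect_multiplier`` is effect_fold^(1 - rho) per
    (taxon, group); ``expected_rpm`` is the composition at the mean log
    abundances scaled to a million.
    """

    expected_log10_rpm: pd.DataFrame
    expected_rpm: pd.DataFrame
    effect_multiplier: pd.DataFrame
    coupling: dict
    seed: int
    design: StudyDesign

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "design": asdict(self.design),
            "coupling": {m: asdict(c) for m, c in self.coupling.items()},
            "expected_log10_rpm": self.expected_log10_rpm.to_dict(),
            "expected_rpm": self.expected_rpm.to_dict(),
            "effect_multiplier": self.effect_multiplier.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _group_mean_log10(
    baseline: np.ndarray, taxa: pd.DataFrame, effects: EffectSpec, group: str
) -> np.ndarray:
    rho = effects.recovery.get(group, 1.0)
    folds = np.array([effects.fold_for(t) for t in taxa.index])
    return baseline + (1.0 - rho) * np.log10(folds)


def generate_study(
    design: StudyDesign,
    effects: EffectSpec | None = None,
    seed: int | None = None,
    low_coverage_samples: tuple[str, ...] = (),
):
    """Generate one synthetic study.

    Parameters
    ----------
    design, effects
        Study shape and planted effects (defaults: :func:`default_effects`).
    seed
        Overrides ``design.seed``; identical (design, effects, seed) give
        byte-identical outputs.
    low_coverage_samples
        Sample ids whose library size is multiplied by 0.01, to exercise
        the low-coverage exclusion path downstream.

    Returns
    -------
    (CountTable, pandas.DataFrame, pandas.DataFrame, StudyTruth)
        Species-level counts with genus annotations; sample metadata
        (group, mouse id, total reads); per-sample marker table (7 immune
        markers, fold units); and the ground truth.
    """
    if effects is None:
        effects = default_effects(design)
    if seed is None:
        seed = design.seed
    unknown = [s for s in low_coverage_samples if s not in design.sample_ids()]
    if unknown:
        raise ConfigError(f"unknown low-coverage sample id(s): {unknown}")

    taxa = _taxa_frame(design)
    for taxon in {**effects.disease_taxa, **effects.health_taxa, **effects.baseline_log10}:
        if taxon not in taxa.index:
            raise ConfigError(f"effect taxon '{taxon}' not among the generated taxa")
    rng = np.random.default_rng(seed)
    n_taxa = len(taxa)
    is_virus = (taxa["kingdom"] == "virus").to_numpy()
    # baseline log10 relative abundance: viruses a decade rarer on average
    baseline = rng.normal(0.0, 0.7, size=n_taxa)
    baseline[is_virus] -= 0.8
    for taxon, b in effects.baseline_log10.items():
        baseline[taxa.index.get_loc(taxon)] = float(b)
    sigma = np.array([effects.sigma_for(t) for t in taxa.index])

    sample_ids = design.sample_ids()
    low = set(low_coverage_samples)
    counts = np.zeros((n_taxa, len(sample_ids)), dtype=np.int64)
    rpm_latent = np.zeros_like(counts, dtype=float)
    meta_rows = []
    col = 0
    for g in design.groups:
        mu = _group_mean_log10(baseline, taxa, effects, g)
        for i in range(1, design.n_per_group + 1):
            sid = f"{g}_{i}"
            a = mu + sigma * rng.normal(size=n_taxa)
            rel = 10.0**a
            rel /= rel.sum()
            lib = design.library_size_mean * (0.01 if sid in low else 1.0)
            n_reads = rng.poisson(lib)
            counts[:, col] = rng.multinomial(max(n_reads, 1), rel)
            rpm_latent[:, col] = rel * 1e6
            meta_rows.append({"sample_id": sid, "group": g, "mouse_id": f"m_{sid}"})
            col += 1

    data = pd.DataFrame(counts, index=taxa.index, columns=sample_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    meta["total_reads"] = data.sum(axis=0)
    table = CountTable(data=data, taxa=taxa, samples=meta)

    # markers: coupled ones follow the realized abundance of their taxon
    totals = data.sum(axis=0).to_numpy()
    markers = pd.DataFrame(index=sample_ids, columns=list(DEFAULT_MARKERS), dtype=float)
    for m in DEFAULT_MARKERS:
        if m in effects.cytokine_coupling:
            c = effects.cytokine_coupling[m]
            if c.taxon not in taxa.index:
                raise ConfigError(f"coupling taxon '{c.taxon}' not in the study taxa")
            rpm_obs = data.loc[c.taxon].to_numpy() / totals * 1e6
            log_m = c.intercept + c.slope * np.log10(rpm_obs + 0.1)
            log_m = log_m + rng.normal(0.0, c.sigma, size=len(sample_ids))
        else:
            log_m = rng.normal(1.0, 0.4, size=len(sample_ids))
        markers[m] = np.maximum(10.0**log_m - 0.1, 0.0)

    truth = _build_truth(design, effects, seed, taxa, baseline, sigma)
    return table, meta, markers, truth


def _build_truth(design, effects, seed, taxa, baseline, sigma) -> StudyTruth:
    # E[log10 RPM] = mu_t - E[log10 sum_t 10^(mu+sigma*eps)] + 6; the
    # normalizing-constant expectation is evaluated by seeded Monte Carlo
    rng = np.random.default_rng([int(seed), 0x7A17])
    exp_log10 = {}
    exp_rpm = {}
    mult = {}
    for g in design.groups:
        mu = _group_mean_log10(baseline, taxa, effects, g)
        draws = mu[None, :] + sigma[None, :] * rng.normal(size=(_TRUTH_MC_DRAWS, len(mu)))
        log_norm = np.log10((10.0**draws).sum(axis=1)).mean()
        exp_log10[g] = mu - log_norm + 6.0
        rel = 10.0**mu
        exp_rpm[g] = rel / rel.sum() * 1e6
        rho = effects.recovery.get(g, 1.0)
        mult[g] = np.array([effects.fold_for(t) ** (1.0 - rho) for t in taxa.index])
    return StudyTruth(
        expected_log10_rpm=pd.DataFrame(exp_log10, index=taxa.index),
        expected_rpm=pd.DataFrame(exp_rpm, index=taxa.index),
        effect_multiplier=pd.DataFrame(mult, index=taxa.index),
        coupling=dict(effects.cytokine_coupling),
        seed=int(seed),
        design=design,
    )


# ---------------------------------------------------------------------------
# host-assay fixtures


@dataclass
class AssayFixtures:
    """Bundle of host-assay fixture tables (all per-mouse / per-group).

    ``bone_loss``: one row per mouse with the 28 site measurements (mm);
    ``defects``: intrabony-defect counts out of 72 surfaces per group;
    ``qpcr``: per-mouse copy numbers for the 4 pathogens plus total 16S;
    ``ct``: per-sample CT values (7 cytokines against GAPDH);
    ``igg``: per-mouse serum IgG OD values.
    """

    bone_loss: pd.DataFrame
    defects: pd.DataFrame
    qpcr: pd.DataFrame
    ct: pd.DataFrame
    igg: pd.DataFrame

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.bone_loss.to_csv(out / "boneloss.tsv", sep="\t", index=False)
        self.defects.to_csv(out / "defects.tsv", sep="\t", index=False)
        self.qpcr.to_csv(out / "qpcr.tsv", sep="\t", index=False)
        self.ct.to_csv(out / "ct.tsv", sep="\t", index=False)
        self.igg.to_csv(out / "igg.tsv", sep="\t", index=False)


def generate_assay_fixtures(
    design: StudyDesign, seed: int | None = None, recovery: dict | None = None
) -> AssayFixtures:
    """Generate the non-sequencing fixtures for every group of the design.

    Group severity follows the same recovery map as the abundance effects:
    full infection shows ~0.40 mm bone loss, ~60% defective surfaces,
    ~2% pathogen load and elevated cytokine expression; control ~0.15 mm,
    ~5%, trace pathogen load and baseline expression; treated groups
    interpolate by 1 - rho.  Deterministic under (design, seed).
    """
    from .assays import BONE_LOSS_SITES, SURFACES_PER_GROUP

    if seed is None:
        seed = design.seed
    if recovery is None:
        recovery = default_recovery(design.groups)
    rng = np.random.default_rng([int(seed), 0xA55A])

    bone_rows, defect_rows, qpcr_rows, ct_rows, igg_rows = [], [], [], [], []
    site_cols = [f"site_{i:02d}" for i in range(1, BONE_LOSS_SITES + 1)]
    for g in design.groups:
        severity = 1.0 - recovery.get(g, 1.0)  # 0 = healthy, 1 = full infection
        bone_mean = 0.15 + 0.25 * severity
        defect_p = 0.05 + 0.55 * severity
        defect_rows.append(
            {
                "group": g,
                "defects": int(rng.binomial(SURFACES_PER_GROUP, defect_p)),
                "total_surfaces": SURFACES_PER_GROUP,
            }
        )
        for i in range(1, design.n_per_group + 1):
            mouse = f"m_{g}_{i}"
            sites = np.maximum(rng.normal(bone_mean, 0.05, size=BONE_LOSS_SITES), 0.0)
            bone_rows.append({"mouse_id": mouse, "group": g, **dict(zip(site_cols, sites))})
            total_16s = float(10 ** rng.normal(6.0, 0.2))
            row = {"mouse_id": mouse, "group": g, "total_16s": total_16s}
            for p in PATHOGENS:
                frac = 0.0001 + 0.02 * severity
                row[p] = float(
                    min(total_16s, total_16s * frac * 10 ** rng.normal(0.0, 0.3))
                )
            qpcr_rows.append(row)
            gapdh = rng.normal(18.0, 0.3)
            for gene in DEFAULT_MARKERS:
                # inflammation lowers dCT (raises expression) by up to ~2 cycles
                dct = 8.0 - 2.0 * severity + rng.normal(0.0, 0.4)
                ct_rows.append(
                    {
                        "sample_id": f"{g}_{i}",
                        "group": g,
                        "gene": gene,
                        "target_ct": gapdh + dct,
                        "gapdh_ct": gapdh,
                    }
                )
            igg_rows.append(
                {
                    "mouse_id": mouse,
                    "group": g,
                    "od": max(rng.normal(0.2 + 1.0 * severity, 0.1), 0.0),
                }
            )
    return AssayFixtures(
        bone_loss=pd.DataFrame(bone_rows),
        defects=pd.DataFrame(defect_rows),
        qpcr=pd.DataFrame(qpcr_rows),
        ct=pd.DataFrame(ct_rows),
        igg=pd.DataFrame(igg_rows),
    )


# ---------------------------------------------------------------------------
# dose arithmetic of the infection/treatment protocol


def combined_inoculum_per_ml(
    cells_per_pathogen: float = 2.5e8,
    n_pathogens: int = 4,
    dose_volume_ml: float = 0.2,
) -> float:
    """Combined inoculum concentration (bacteria/ml) of the oral dose.

    Four pathogens at 2.5e8 cells each in a 0.2 ml dose give 1e9 cells per
    mouse, i.e. 5e9 combined bacteria per ml.
    """
    if cells_per_pathogen <= 0 or n_pathogens < 1 or dose_volume_ml <= 0:
        raise ConfigError("dose parameters must be positive")
    return cells_per_pathogen * n_pathogens / dose_volume_ml


def equal_volume_mix(stock_concentration: float) -> float:
    """Final concentration after mixing a stock 1:1 with carrier (2x dilution).

    E.g. a 600 ug/ml nisin stock mixed with an equal volume of 4% CMC
    gives 300 ug/ml; a 1e10 CFU/ml probiotic suspension gives 5e9/ml.
    """
    if stock_concentration < 0:
        raise ConfigError("concentration must be nonnegative")
    return stock_concentration / 2.0
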