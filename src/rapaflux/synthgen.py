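"""Synthetic metabolomic datasets and the bundled toy metabolic network.

The raw intracellular metabolomics of the elicitor study are not publicly
deposited, so this module generates datasets with the same design -- four
treatments (control, DMSO, LaCl3, sodium butyrate) sampled 12/24/48 h after
elicitor feeding with four biological replicates, 93 metabolites (83 GC-MS
plus 10 LC-MS sugar phosphates) -- and with planted statistical structure:
treatment-responsive co-response modules and a rapamycin-yield trait driven
by phosphoenolpyruvate and pyruvate.  Every downstream stage of the pipeline
is exercised against this substrate.

A compact surrogate metabolic network (central carbon metabolism, PP pathway,
aspartate/lysine route, shikimate branch and a lumped rapamycin synthase) is
also built here for the constraint-based screening stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (EmptyInputError, FormatError, NamedEntityError,
                         ValidationError)
from .gsmm import MetabolicModel, Reaction

# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------

#: Relative strength of the elicitor response at each sampling time; the
#: response peaks 24 h after feeding, where treatments separate most clearly.
TIME_RESPONSE = {12: 0.6, 24: 1.0, 48: 0.7}


@dataclass(frozen=True)
class StudyDesign:
    """Factorial sampling design of the elicitor-feeding experiment."""

    conditions: tuple[str, ...] = ("control", "DMSO", "LaCl3", "SB")
    timepoints_h: tuple[int, ...] = (12, 24, 48)
    n_replicates: int = 4
    feed_time_h: int = 72

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        if list(self.timepoints_h) != sorted(set(self.timepoints_h)):
            raise ValidationError("timepoints must be strictly increasing")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValidationError("condition labels must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.conditions) * len(self.timepoints_h) * self.n_replicates

    def sample_table(self) -> pd.DataFrame:
        rows = [
            {"sample_id": f"{c}_t{t}_r{r}", "condition": c,
             "timepoint_h": t, "replicate": r}
            for c in self.conditions
            for t in self.timepoints_h
            for r in range(1, self.n_replicates + 1)
        ]
        return pd.DataFrame(rows).set_index("sample_id")


@dataclass(frozen=True)
class PlantedModuleSpec:
    """A co-response module planted into the synthetic data."""

    module_id: str
    member_metabolites: tuple[str, ...]
    responsive_condition: str
    effect_size: float = 1.0          # mean log10-abundance shift at 24 h
    within_module_cor: float = 0.84   # target pairwise Pearson r of members

    def __post_init__(self):
        if not 0.0 <= self.within_module_cor < 1.0:
            raise ValidationError("within_module_cor must lie in [0, 1)")


# ---------------------------------------------------------------------------
# metabolite panel (93 = 83 GC-MS + 10 LC-MS sugar phosphates)
# ---------------------------------------------------------------------------

MODULE_M1 = (
    "trehalose", "dodecanoic acid", "decanedioic acid", "glucose",
    "glyoxylic acid", "glycerol", "fructose 6-phosphate", "arabinal",
    "1,3-butanediol", "octadecanoic acid", "putrescine",
)
MODULE_M2 = (
    "methylmalonate", "nonanoic acid", "niacinamide", "6-phospho-D-gluconate",
    "docosanoic acid", "hexadecanoic acid", "fructose 1,6-bisphosphate",
    "nonanedioic acid", "nicotinate", "tetradecanoic acid",
    "glucose 6-phosphate", "malonic acid", "2-oxobutanoate",
)
MODULE_M3 = (
    "allothreonine", "phenylalanine", "tyrosine", "aspartic acid", "threonine",
    "lactate", "isoleucine", "cadaverine", "norleucine", "acetoin", "butanal",
)
MODULE_M4 = (
    "proline", "shikimate", "glucitol", "lysine", "indole",
    "xylulose 5-phosphate", "tryptophan", "rhamnose", "picolinic acid",
    "pentanoic acid", "linoleic acid", "ribulose 5-phosphate",
    "sedoheptulose 7-phosphate", "ethanol", "erythrose 4-phosphate",
    "ethanedioic acid", "alanine",
)

_EXTRA_NAMED = (
    "phosphoenolpyruvate", "pyruvate", "glyceraldehyde 3-phosphate",
    "glycerate 3-phosphate", "hexadecenoic acid", "succinate",
)

_PADDING = (
    "glycine", "serine", "valine", "leucine", "methionine", "glutamate",
    "glutamine", "asparagine", "histidine", "arginine", "citrate", "malate",
    "fumarate", "2-oxoglutarate", "ribose 5-phosphate", "glucose 1-phosphate",
    "mannose", "xylose", "arabinose", "galactose", "myo-inositol", "glycerate",
    "uracil", "uridine", "adenine", "adenosine", "hypoxanthine", "xanthine",
    "urea", "ornithine", "4-aminobutyrate", "benzoate", "decanoic acid",
    "heptadecanoic acid", "2-hydroxybutanoate",
)

#: Sugar phosphates quantified by LC-MS/MS; everything else is GC-MS.
LCMS_SUGAR_PHOSPHATES = (
    "fructose 6-phosphate", "6-phospho-D-gluconate",
    "fructose 1,6-bisphosphate", "glucose 6-phosphate",
    "xylulose 5-phosphate", "ribulose 5-phosphate",
    "sedoheptulose 7-phosphate", "erythrose 4-phosphate",
    "ribose 5-phosphate", "glucose 1-phosphate",
)


def default_metabolite_panel() -> list[str]:
    """The 93-metabolite panel: module members, named drivers, padding."""
    panel = list(MODULE_M1 + MODULE_M2 + MODULE_M3 + MODULE_M4
                 + _EXTRA_NAMED + _PADDING)
    assert len(panel) == len(set(panel)) == 93
    return panel


def metabolite_platforms(panel: list[str] | None = None) -> pd.Series:
    panel = panel if panel is not None else default_metabolite_panel()
    return pd.Series(
        ["LC-MS" if m in LCMS_SUGAR_PHOSPHATES else "GC-MS" for m in panel],
        index=panel, name="platform")


def default_planted_modules() -> list[PlantedModuleSpec]:
    """Four treatment-responsive modules: DMSO (M1), SB (M2, M3), LaCl3 (M4).

    Effect sizes mirror the observed association pattern -- the DMSO and
    LaCl3 modules respond more strongly than the two sodium-butyrate
    modules -- which also keeps the two SB modules statistically separable.
    """
    return [
        PlantedModuleSpec("M1", MODULE_M1, "DMSO", effect_size=1.4),
        PlantedModuleSpec("M2", MODULE_M2, "SB", effect_size=1.25),
        PlantedModuleSpec("M3", MODULE_M3, "SB", effect_size=1.25),
        PlantedModuleSpec("M4", MODULE_M4, "LaCl3", effect_size=1.5),
    ]


#: Final rapamycin titers per condition (arbitrary titer units) and their CV.
DEFAULT_YIELD_MEANS = {"control": 112.59, "DMSO": 161.16,
                       "LaCl3": 157.03, "SB": 151.80}
YIELD_CV = 0.05

#: Weights of the standardized driver metabolites in the yield trait.
DEFAULT_YIELD_LINK = {"phosphoenolpyruvate": 25.0, "pyruvate": 20.0}


# ---------------------------------------------------------------------------
# dataset container and IO
# ---------------------------------------------------------------------------

@dataclass
class MetaboliteDataset:
    """Sample x metabolite intensities with per-sample metadata and a yield trait."""

    intensities: pd.DataFrame        # samples x metabolites
    metadata: pd.DataFrame           # condition, timepoint_h, replicate, yield
    platform: pd.Series | None = None
    normalized: bool = False

    REQUIRED_METADATA = ("condition", "timepoint_h", "replicate", "yield")

    def validate(self) -> None:
        if self.intensities.shape[0] == 0:
            raise EmptyInputError("dataset has no samples")
        if self.intensities.shape[1] == 0:
            raise EmptyInputError("dataset has no metabolites")
        if list(self.intensities.index) != list(self.metadata.index):
            raise ValidationError("intensity and metadata sample IDs differ")
        if self.intensities.index.duplicated().any():
            raise ValidationError("duplicate sample IDs")
        if self.intensities.columns.duplicated().any():
            raise ValidationError("duplicate metabolite names")
        for col in self.REQUIRED_METADATA:
            if col not in self.metadata.columns:
                raise ValidationError(f"metadata misses required column '{col}'")
            if self.metadata[col].isna().any():
                raise ValidationError(f"metadata column '{col}' has missing values")
        if not self.normalized and (self.intensities.to_numpy() < 0).any():
            raise ValidationError("negative intensities in a raw dataset")

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def metabolites(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def yields(self) -> pd.Series:
        return self.metadata["yield"]

    def subset_timepoint(self, timepoint_h: int) -> "MetaboliteDataset":
        mask = self.metadata["timepoint_h"] == timepoint_h
        return MetaboliteDataset(
            intensities=self.intensities.loc[mask].copy(),
            metadata=self.metadata.loc[mask].copy(),
            platform=self.platform, normalized=self.normalized)

    def equals(self, other: "MetaboliteDataset") -> bool:
        same = (self.intensities.equals(other.intensities)
                and self.metadata.equals(other.metadata))
        if self.platform is not None and other.platform is not None:
            same = same and self.platform.equals(other.platform)
        return bool(same)


def generate_dataset(
    design: StudyDesign | None = None,
    modules: list[PlantedModuleSpec] | None = None,
    noise_sd: float = 0.3,
    yield_link: dict[str, float] | None = None,
    seed: int = 0,
    metabolites: list[str] | None = None,
) -> MetaboliteDataset:
    """Simulate an intensity matrix with planted modules and a yield trait.

    Members of a planted module share a per-sample latent factor whose mean is
    shifted by ``effect_size`` (on the log10 scale, tapered by the sampling
    time response) in the module's responsive condition; the latent variance
    is calibrated so the expected pairwise within-module Pearson correlation
    over the whole design equals ``within_module_cor``.  Non-member
    metabolites are independent log-normal noise.  The yield trait is the
    per-condition mean titer plus weighted standardized driver abundances
    (``yield_link``) plus Gaussian error (5% CV).
    """
    design = design if design is not None else StudyDesign()
    modules = modules if modules is not None else default_planted_modules()
    yield_link = yield_link if yield_link is not None else dict(DEFAULT_YIELD_LINK)
    panel = metabolites if metabolites is not None else default_metabolite_panel()
    if noise_sd < 0:
        raise ValidationError("noise_sd must be nonnegative")

    seen: set[str] = set()
    for spec in modules:
        members = set(spec.member_metabolites)
        unknown = members - set(panel)
        if unknown:
            raise NamedEntityError(
                f"module '{spec.module_id}' plants unknown metabolites: "
                f"{sorted(unknown)}")
        if members & seen:
            raise ValidationError(
                f"module '{spec.module_id}' overlaps another module's members")
        if spec.responsive_condition not in design.conditions:
            raise NamedEntityError(
                f"module '{spec.module_id}' responds to unknown condition "
                f"'{spec.responsive_condition}'")
        seen |= members
    unknown_drivers = set(yield_link) - set(panel)
    if unknown_drivers:
        raise NamedEntityError(f"yield_link names unknown metabolites: "
                               f"{sorted(unknown_drivers)}")

    meta = design.sample_table()
    n, p = len(meta), len(panel)
    rng = np.random.default_rng(seed)

    # baseline log10 abundances, stable given the seed
    baseline = rng.uniform(4.0, 6.0, size=p)
    log_x = np.tile(baseline, (n, 1)) + rng.normal(0.0, noise_sd, size=(n, p))

    col = {m: j for j, m in enumerate(panel)}
    tresp = meta["timepoint_h"].map(
        lambda t: TIME_RESPONSE.get(int(t), 1.0)).to_numpy(float)

    for spec in modules:
        shift = (spec.effect_size * tresp
                 * (meta["condition"] == spec.responsive_condition).to_numpy(float))
        var_shift = float(np.var(shift))  # population variance over the design
        rho = spec.within_module_cor
        if noise_sd == 0.0:
            latent_sd = 0.1  # any shared variance gives exact correlation 1
        else:
            latent_var = rho / (1.0 - rho) * noise_sd ** 2 - var_shift
            if latent_var < 0:
                warnings.warn(
                    f"module '{spec.module_id}': planted shift already exceeds "
                    f"the correlation target; shared factor clipped to 0")
                latent_var = 0.0
            latent_sd = float(np.sqrt(latent_var))
        shared = shift + rng.normal(0.0, latent_sd, size=n)
        for m in spec.member_metabolites:
            j = col[m]
            log_x[:, j] = baseline[j] + shared + rng.normal(0.0, noise_sd, size=n)

    intensities = pd.DataFrame(10.0 ** log_x, index=meta.index, columns=panel)

    cond_mean = meta["condition"].map(DEFAULT_YIELD_MEANS).astype(float)
    if cond_mean.isna().any():  # non-default condition labels: flat baseline
        cond_mean = cond_mean.fillna(float(np.mean(list(DEFAULT_YIELD_MEANS.values()))))
    y = cond_mean.to_numpy(float).copy()
    for m, w in yield_link.items():
        z = log_x[:, col[m]]
        sd = z.std(ddof=1)
        if sd > 0:
            y += w * (z - z.mean()) / sd
    y += rng.normal(0.0, YIELD_CV * cond_mean.to_numpy(float))

    metadata = meta.copy()
    metadata["yield"] = y
    ds = MetaboliteDataset(intensities=intensities, metadata=metadata,
                           platform=metabolite_platforms(panel)
                           if metabolites is None else None)
    ds.validate()
    return ds


# -- TSV round trip ---------------------------------------------------------

def write_dataset(ds: MetaboliteDataset, directory) -> None:
    """Write intensities.tsv + metadata.tsv (+ metabolites.tsv if annotated)."""
    ds.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ds.intensities.to_csv(directory / "intensities.tsv", sep="\t",
                          index_label="sample_id")
    ds.metadata.to_csv(directory / "metadata.tsv", sep="\t",
                       index_label="sample_id")
    if ds.platform is not None:
        ds.platform.rename_axis("metabolite").to_csv(
            directory / "metabolites.tsv", sep="\t")


def read_dataset(directory, normalized: bool = False) -> MetaboliteDataset:
    directory = Path(directory)
    try:
        intensities = pd.read_csv(directory / "intensities.tsv", sep="\t",
                                  index_col="sample_id",
                                  float_precision="round_trip")
        metadata = pd.read_csv(directory / "metadata.tsv", sep="\t",
                               index_col="sample_id",
                               float_precision="round_trip")
    except FileNotFoundError as exc:
        raise FormatError(f"missing dataset file: {exc}") from exc
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"malformed dataset TSV: {exc}") from exc
    platform_path = directory / "metabolites.tsv"
    platform = None
    if platform_path.exists():
        platform = pd.read_csv(platform_path, sep="\t",
                               index_col="metabolite")["platform"]
        platform.index.name = None
    for col in MetaboliteDataset.REQUIRED_METADATA:
        if col not in metadata.columns:
            raise FormatError(f"metadata.tsv misses required column '{col}'")
    ds = MetaboliteDataset(intensities=intensities, metadata=metadata,
                           platform=platform, normalized=normalized)
    try:
        ds.validate()
    except (ValidationError, EmptyInputError) as exc:
        if isinstance(exc, EmptyInputError):
            raise
        raise FormatError(str(exc)) from exc
    return ds


# ---------------------------------------------------------------------------
# toy metabolic network
# ---------------------------------------------------------------------------

#: Perturbations screened by default: the curated target set of the bundled
#: network, each with its intended engineering strategy.
DEFAULT_SCREEN_CANDIDATES: list[tuple[str, str]] = [
    ("r532", "overexpression"),   # DAHP synthase (aroA)
    ("r279", "knockout"),         # glutamate dehydrogenase, NADP+ (gdhA)
    ("r47", "overexpression"),    # transketolase (tktB)
    ("r51", "overexpression"),    # glucose-6-phosphate 1-dehydrogenase (zwf2)
    ("r381", "knockout"),         # glutaryl-CoA dehydrogenase
    ("r274", "overexpression"),   # aspartate aminotransferase
    ("r18", "knockout"),          # PEP carboxylase
    ("r23", "knockout"),          # pyruvate carboxylase
    ("r293", "overexpression"),   # dihydrodipicolinate synthase
    ("r421", "overexpression"),   # aspartate kinase
]


def build_toy_model() -> MetabolicModel:
    """A ~50-reaction surrogate network for rapamycin-producing *Streptomyces*.

    Central glycolysis, NAD-linked TCA lump, oxidative/non-oxidative pentose
    phosphate pathway, GDH and GS/GOGAT nitrogen assimilation, the aspartate ->
    lysine -> pipecolate route with a lysine-degradation branch, the shikimate
    branch to the DHCHC starter unit, methylmalonyl-CoA supply, and a lumped
    rapamycin synthase (1 DHCHC + 7 methylmalonyl-CoA + 1 pipecolate + NADPH).
    Phosphate uptake is the growth-limiting nutrient under the measured
    constraints, while glucose is in excess, leaving slack for flux
    redistribution toward the product after perturbations.
    """
    mets = {
        "glc": "D-glucose", "g6p": "D-glucose 6-phosphate",
        "f6p": "D-fructose 6-phosphate", "fdp": "D-fructose 1,6-bisphosphate",
        "g3p": "glyceraldehyde 3-phosphate", "pep": "phosphoenolpyruvate",
        "pyr": "pyruvate", "accoa": "acetyl-CoA", "mmcoa": "methylmalonyl-CoA",
        "oaa": "oxaloacetate", "akg": "2-oxoglutarate", "glu": "L-glutamate",
        "gln": "L-glutamine", "asp": "L-aspartate",
        "asp4p": "L-aspartyl-4-phosphate", "aspsa": "L-aspartate semialdehyde",
        "dhdp": "L-2,3-dihydrodipicolinate", "lys": "L-lysine",
        "pip": "L-pipecolate", "glutcoa": "glutaryl-CoA",
        "crotcoa": "crotonyl-CoA",
        "dahp": "3-deoxy-D-arabino-heptulosonate 7-phosphate",
        "chor": "chorismate", "phe": "L-phenylalanine",
        "dhchc": "4,5-dihydroxycyclohex-1-ene carboxylate (DHCHC)",
        "rapa": "rapamycin", "e4p": "D-erythrose 4-phosphate",
        "x5p": "D-xylulose 5-phosphate", "ru5p": "D-ribulose 5-phosphate",
        "r5p": "D-ribose 5-phosphate", "s7p": "sedoheptulose 7-phosphate",
        "pgl": "D-6-phosphogluconolactone", "pgc": "6-phospho-D-gluconate",
        "nad": "NAD+", "nadh": "NADH", "nadp": "NADP+", "nadph": "NADPH",
        "atp": "ATP", "adp": "ADP", "pi": "phosphate", "nh3": "ammonia",
        "hco3": "bicarbonate", "co2": "CO2", "h2o": "H2O", "o2": "O2",
        "h": "H+",
    }

    def rxn(rid, name, stoich, lb=0.0, ub=1000.0, rev=False):
        return Reaction(rid, name, stoich, lb, ub, rev)

    reactions = [
        # exchanges (uptake direction = positive flux for nutrients)
        rxn("EX_glc", "glucose exchange", {"glc": 1}, 0, 10),
        rxn("EX_nh3", "ammonium exchange", {"nh3": 1}, 0, 10),
        rxn("EX_pi", "phosphate exchange", {"pi": 1}, 0, 10),
        # respiratory capacity cap: keeps ATP supply tight enough that the
        # NADP-GDH route (not the ATP/NADH-costly GS/GOGAT cycle) carries
        # nitrogen assimilation at the wild-type optimum
        rxn("EX_o2", "oxygen exchange", {"o2": 1}, 0, 0.36),
        rxn("EX_co2", "CO2 exchange", {"co2": -1}, 0, 1000),
        rxn("EX_h2o", "water exchange", {"h2o": -1}, -1000, 1000, rev=True),
        rxn("EX_h", "proton exchange", {"h": -1}, -1000, 1000, rev=True),
        rxn("EX_rapa", "rapamycin exchange", {"rapa": -1}, 0, 1000),
        # glycolysis
        rxn("HEX", "hexokinase",
            {"glc": -1, "atp": -1, "g6p": 1, "adp": 1, "h": 1}),
        rxn("PGI", "phosphoglucose isomerase",
            {"g6p": -1, "f6p": 1}, -1000, 1000, rev=True),
        rxn("PFK", "phosphofructokinase",
            {"f6p": -1, "atp": -1, "fdp": 1, "adp": 1, "h": 1}),
        rxn("ALD", "aldolase + triose isomerase", {"fdp": -1, "g3p": 2}),
        rxn("GAPDH", "GAPDH + PGK + enolase (lumped)",
            {"g3p": -1, "pi": -1, "nad": -1, "adp": -1,
             "pep": 1, "atp": 1, "nadh": 1, "h2o": 1}),
        rxn("PYK", "pyruvate kinase",
            {"pep": -1, "adp": -1, "h": -1, "pyr": 1, "atp": 1}),
        rxn("PDH", "pyruvate dehydrogenase",
            {"pyr": -1, "nad": -1, "accoa": 1, "nadh": 1, "co2": 1}),
        # TCA (two lumps) + respiration
        rxn("CSICD", "citrate synthase -> isocitrate dehydrogenase (lumped)",
            {"accoa": -1, "oaa": -1, "h2o": -1, "nad": -1,
             "akg": 1, "co2": 1, "nadh": 1}),
        rxn("AKGDH", "2-oxoglutarate -> oxaloacetate (lumped)",
            {"akg": -1, "nad": -2, "adp": -1, "pi": -1,
             "oaa": 1, "nadh": 2, "atp": 1, "co2": 1}),
        rxn("OXPHOS", "oxidative phosphorylation (P/O = 2)",
            {"nadh": -1, "o2": -0.5, "adp": -2, "pi": -2, "h": -1,
             "nad": 1, "atp": 2, "h2o": 2}),
        rxn("ATPM", "ATP maintenance",
            {"atp": -1, "h2o": -1, "adp": 1, "pi": 1, "h": 1}, 0.01, 1000),
        # pentose phosphate pathway
        rxn("r51", "glucose-6-phosphate 1-dehydrogenase",
            {"g6p": -1, "nadp": -1, "pgl": 1, "nadph": 1, "h": 1}),
        rxn("PGLS", "6-phosphogluconolactonase",
            {"pgl": -1, "h2o": -1, "pgc": 1, "h": 1}),
        rxn("GND", "6-phosphogluconate dehydrogenase",
            {"pgc": -1, "nadp": -1, "ru5p": 1, "nadph": 1, "co2": 1}),
        rxn("RPE", "ribulose-5-phosphate epimerase",
            {"ru5p": -1, "x5p": 1}, -1000, 1000, rev=True),
        rxn("RPI", "ribose-5-phosphate isomerase",
            {"ru5p": -1, "r5p": 1}, -1000, 1000, rev=True),
        rxn("TKT1", "transketolase (R5P + X5P)",
            {"r5p": -1, "x5p": -1, "s7p": 1, "g3p": 1}, -1000, 1000, rev=True),
        rxn("TAL", "transaldolase",
            {"s7p": -1, "g3p": -1, "e4p": 1, "f6p": 1}, -1000, 1000, rev=True),
        rxn("r47", "transketolase (E4P + X5P)",
            {"e4p": -1, "x5p": -1, "f6p": 1, "g3p": 1}),
        # anaplerosis
        rxn("r18", "phosphoenolpyruvate carboxylase",
            {"pep": -1, "co2": -1, "h2o": -1, "pi": 1, "oaa": 1}),
        rxn("r23", "pyruvate carboxylase",
            {"hco3": -1, "pyr": -1, "atp": -1, "pi": 1, "oaa": 1, "adp": 1}),
        rxn("CA", "carbonic anhydrase",
            {"co2": -1, "h2o": -1, "hco3": 1, "h": 1}, -1000, 1000, rev=True),
        # nitrogen assimilation
        rxn("r279", "glutamate dehydrogenase (NADP+)",
            {"nh3": -1, "akg": -1, "nadph": -1, "h": -1,
             "glu": 1, "nadp": 1, "h2o": 1}),
        rxn("GS", "glutamine synthetase",
            {"glu": -1, "nh3": -1, "atp": -1, "gln": 1, "adp": 1, "pi": 1}),
        rxn("GOGAT", "glutamate synthase (NADH)",
            {"gln": -1, "akg": -1, "nadh": -1, "h": -1, "glu": 2, "nad": 1}),
        # aspartate -> lysine -> pipecolate
        rxn("r274", "aspartate aminotransferase",
            {"oaa": -1, "glu": -1, "asp": 1, "akg": 1}),
        rxn("r421", "aspartate kinase",
            {"asp": -1, "atp": -1, "asp4p": 1, "adp": 1}),
        rxn("ASD", "aspartate-semialdehyde dehydrogenase",
            {"asp4p": -1, "nadph": -1, "h": -1,
             "aspsa": 1, "nadp": 1, "pi": 1}),
        rxn("r293", "dihydrodipicolinate synthase",
            {"pyr": -1, "aspsa": -1, "h2o": 2, "dhdp": 1}),
        rxn("LYSS", "diaminopimelate route to lysine (lumped)",
            {"dhdp": -1, "nadph": -1, "glu": -1, "h": -1,
             "lys": 1, "akg": 1, "nadp": 1, "co2": 1}),
        rxn("PIPS", "lysine cyclodeaminase",
            {"lys": -1, "pip": 1, "nh3": 1}),
        rxn("LYSDEG", "lysine degradation to glutaryl-CoA (lumped)",
            {"lys": -1, "nad": -2, "h2o": -1,
             "glutcoa": 1, "nh3": 2, "nadh": 2, "co2": 1}),
        rxn("r381", "glutaryl-CoA dehydrogenase",
            {"glutcoa": -1, "nad": -2, "crotcoa": 1, "nadh": 2, "co2": 1}),
        rxn("CROTDEG", "crotonyl-CoA to acetyl-CoA (lumped beta-oxidation)",
            {"crotcoa": -1, "h2o": -1, "nad": -1, "accoa": 2, "nadh": 1}),
        # methylmalonyl-CoA supply
        rxn("MMS", "methylmalonyl-CoA supply from pyruvate (lumped)",
            {"pyr": -1, "hco3": -1, "atp": -1, "nadph": -1,
             "mmcoa": 1, "adp": 1, "pi": 1, "nadp": 1}),
        # shikimate branch and product
        rxn("r532", "2-dehydro-3-deoxyphosphoheptonate aldolase",
            {"pep": -1, "e4p": -1, "h2o": -1, "dahp": 1, "pi": 1}),
        rxn("CHORS", "DAHP to chorismate (lumped shikimate pathway)",
            {"dahp": -1, "pep": -1, "atp": -1, "nadph": -1,
             "chor": 1, "adp": 1, "nadp": 1, "pi": 3}),
        rxn("PHES", "chorismate to phenylalanine (lumped)",
            {"chor": -1, "glu": -1, "phe": 1, "akg": 1, "h2o": 1, "co2": 1}),
        rxn("DHCHCS", "chorismate to DHCHC starter unit (lumped)",
            {"chor": -1, "nadph": -1, "h": -1, "dhchc": 1, "nadp": 1}),
        rxn("RAPS", "rapamycin synthase (lumped PKS/NRPS)",
            {"dhchc": -1, "mmcoa": -7, "pip": -1, "nadph": -4, "h": -4,
             "rapa": 1, "nadp": 4, "co2": 7}),
        # biomass: P content calibrated to the measured phosphate uptake
        rxn("BIOMASS", "biomass synthesis",
            {"g6p": -0.03, "pep": -0.02, "r5p": -0.03, "pyr": -0.15,
             "accoa": -0.25, "oaa": -0.10, "akg": -0.08, "glu": -0.25,
             "asp": -0.12, "lys": -0.05, "phe": -0.04,
             "nadph": -0.5, "nadp": 0.5,
             "atp": -30, "adp": 30, "h2o": -30, "pi": 29.949, "h": 30}),
    ]
    model = MetabolicModel(
        metabolites=mets,
        reactions={r.id: r for r in reactions},
        objective_id="BIOMASS",
        rapamycin_exchange_id="EX_rapa",
    )
    model.validate()
    return model
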