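"""Synthetic two-arm longitudinal infant cohort generator.

Emulates the structure of a randomized EHF feeding trial in infants: ~130
infants enrolled between 2 weeks and 6 months of age, randomized 1:1 to a
control or an HMO-supplemented test formula, sampled at enrollment (V0),
one month (V1) and three months (V3) after enrollment, and at 365 days of
age (V6).  Each infant carries a latent fecal community type (FCT)
trajectory: a forward-only jump process FCT1 -> ... -> FCT5 with
per-transition exponential waiting times whose hazards are multiplied by a
treatment hazard ratio (< 1 slows maturation) in the test arm.  Observed
genus counts are Dirichlet-multinomial draws from the latent FCT's alpha
vector; metabolite and bile-acid concentrations are log-normal with
locations keyed by (FCT, arm); KO relative abundances are noisy monotone
functions of the latent FCT.

Sequencing depth is drawn from a negative binomial around 20,000 reads —
far below real shotgun depth, since the community-typing model operates on
count composition, not absolute depth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import (KOAbundanceMatrix, MetaboliteMatrix, SampleTable,
                     TaxaCountMatrix, assign_cohort)


class ConfigError(ValueError):
    """Raised when a cohort configuration field is invalid."""


GENERA = (
    "Escherichia", "Klebsiella", "Enterobacter", "Citrobacter", "Haemophilus",
    "Staphylococcus", "Streptococcus", "Enterococcus", "Lactobacillus",
    "Bifidobacterium", "Collinsella", "Veillonella", "Clostridium",
    "Clostridioides", "Lachnoclostridium", "Blautia", "Dorea", "Eubacterium",
    "Anaerostipes", "Roseburia", "Ruminococcus", "Faecalibacterium",
    "Flavonifractor", "Hungatella", "Erysipelatoclostridium", "Bacteroides",
    "Parabacteroides", "Prevotella", "Alistipes", "Akkermansia",
)


def _default_alpha_matrix() -> np.ndarray:
    """Five separable community types over 30 genera.

    FCT1: proteobacteria-dominated newborn community; FCT2: bifidobacteria
    (milk-adapted); FCT3: early clostridia; FCT4: mixed firmicutes; FCT5:
    mature, Faecalibacterium-rich.  Pairwise Bray-Curtis between component
    mean compositions is >= 0.5.
    """
    T = len(GENERA)
    base = np.full((5, T), 0.05)
    idx = {g: j for j, g in enumerate(GENERA)}

    def load(k, pairs):
        for genus, a in pairs:
            base[k, idx[genus]] = a

    load(0, [("Escherichia", 12.0), ("Klebsiella", 6.0), ("Enterobacter", 3.0),
             ("Citrobacter", 2.0), ("Staphylococcus", 1.5), ("Streptococcus", 1.5),
             ("Haemophilus", 1.0)])
    load(1, [("Bifidobacterium", 14.0), ("Veillonella", 4.0), ("Lactobacillus", 2.0),
             ("Streptococcus", 2.0), ("Collinsella", 1.5)])
    load(2, [("Lachnoclostridium", 8.0), ("Clostridium", 4.0), ("Blautia", 3.0),
             ("Bacteroides", 3.0), ("Enterococcus", 1.5), ("Hungatella", 1.0)])
    load(3, [("Ruminococcus", 6.0), ("Blautia", 5.0), ("Dorea", 3.0),
             ("Eubacterium", 3.0), ("Anaerostipes", 2.0), ("Roseburia", 2.0)])
    load(4, [("Faecalibacterium", 9.0), ("Roseburia", 4.0), ("Alistipes", 3.0),
             ("Bacteroides", 3.0), ("Akkermansia", 2.0), ("Prevotella", 1.5),
             ("Parabacteroides", 1.5)])
    return base


#: Phylum-level clade blocks used to build the default genus tree.
_CLADES = (
    ("Escherichia", "Klebsiella", "Enterobacter", "Citrobacter", "Haemophilus"),
    ("Staphylococcus", "Streptococcus", "Enterococcus", "Lactobacillus"),
    ("Bifidobacterium", "Collinsella"),
    ("Veillonella", "Clostridium", "Clostridioides", "Lachnoclostridium",
     "Blautia", "Dorea", "Eubacterium", "Anaerostipes", "Roseburia",
     "Ruminococcus", "Faecalibacterium", "Flavonifractor", "Hungatella",
     "Erysipelatoclostridium"),
    ("Bacteroides", "Parabacteroides", "Prevotella", "Alistipes"),
    ("Akkermansia",),
)


def default_genus_tree_newick() -> str:
    """Newick tree over the default genera: one clade per phylum block,
    grouped under a rooted (binary) backbone.

    Branch lengths are fixed (leaves 0.5, stems 1.0) — enough phylogenetic
    structure for Faith's PD to reward taxonomically diverse communities,
    with no pretence of a real genus phylogeny.
    """
    clades = []
    for block in _CLADES:
        tips = ",".join(f"{g}:0.5" for g in block)
        clades.append(f"({tips}):1.0" if len(block) > 1 else f"({block[0]}:0.5):1.0")
    # gram-negative-ish side: proteobacteria, bacteroidetes, verrucomicrobia
    left = f"({clades[0]},{clades[4]},{clades[5]}):1.0"
    # gram-positive side: bacilli, actinobacteria, clostridia
    right = f"({clades[1]},{clades[2]},{clades[3]}):1.0"
    return f"({left},{right});"


#: 43-analyte bile-acid panel (unconjugated, glyco- and tauro-conjugated,
#: sulfated and oxo forms), quantified in nmol/g.
BILE_ACID_PANEL = (
    "CA", "CDCA", "DCA", "LCA", "UDCA", "HDCA", "HCA",
    "7-ketoDCA", "12-ketoLCA", "7-ketoLCA", "6,7-diketoLCA",
    "Dehydrocholic acid", "isoLCA", "alloLCA", "isoDCA", "NorCA", "NorDCA",
    "3-oxoCA", "3-oxoCDCA", "betaMCA",
    "GCA", "GCDCA", "GDCA", "GLCA", "GUDCA", "GHCA", "GHDCA",
    "TCA", "TCDCA", "TDCA", "TLCA", "TUDCA", "THDCA", "THCA",
    "TalphaMCA", "TbetaMCA", "TomegaMCA",
    "LCA-3S", "GLCA-3S", "TLCA-3S", "CA-7S", "alphaMCA", "omegaMCA",
)


def _scaled(levels, factor):
    return [x * factor for x in levels]


def _default_metabolite_spec() -> dict:
    """Log-normal location (median, nmol/g) per FCT and arm, plus log-sd.

    The control-arm 2'-FL trace mirrors measured background levels (86
    nmol/g in the earliest community state, 64 in the next, under 20
    later); the test arm carries the supplementation signal.  Proteolytic
    (Ehrlich-pathway) catabolites rise with later FCTs and are suppressed
    in the test arm; SCFAs follow maturation with no arm effect.
    """
    spec = {
        "2'-Fucosyllactose": {"control": [86, 64, 18, 12, 8],
                              "test": [1600, 1500, 420, 300, 200], "sigma": 0.6},
        "Lacto-N-neotetraose": {"control": [20, 15, 8, 5, 4],
                                "test": [420, 380, 150, 100, 80], "sigma": 0.6},
        "Lactose": {"control": [900, 700, 400, 300, 250],
                    "test": [1620, 1260, 720, 540, 450], "sigma": 0.5},
        "Hydroxybenzoic acid": {"control": [6, 7, 8, 9, 10],
                                "test": [12, 14, 16, 18, 20], "sigma": 0.5},
        "Phenylacetic acid": {"control": [40, 60, 120, 160, 200], "sigma": 0.7,
                              "test": _scaled([40, 60, 120, 160, 200], 0.30)},
        "2-Hydroxyphenylacetic acid": {"control": [10, 15, 30, 40, 50], "sigma": 0.7,
                                       "test": _scaled([10, 15, 30, 40, 50], 0.35)},
        "3-Hydroxyphenylacetic acid": {"control": [12, 18, 35, 48, 60], "sigma": 0.7,
                                       "test": _scaled([12, 18, 35, 48, 60], 0.30)},
        "4-Cresol sulfate": {"control": [25, 35, 80, 110, 140], "sigma": 0.7,
                             "test": _scaled([25, 35, 80, 110, 140], 0.35)},
        "Hydrocinnamic acid": {"control": [8, 12, 25, 35, 45], "sigma": 0.7,
                               "test": _scaled([8, 12, 25, 35, 45], 0.25)},
        "L-Phenylalanine": {"control": [300, 320, 380, 420, 450], "sigma": 0.5,
                            "test": _scaled([300, 320, 380, 420, 450], 0.55)},
        "Isobutyric acid": {"control": [150, 200, 400, 520, 650], "sigma": 0.6,
                            "test": _scaled([150, 200, 400, 520, 650], 0.40)},
        "Isovaleric acid": {"control": [90, 130, 280, 380, 480], "sigma": 0.6,
                            "test": _scaled([90, 130, 280, 380, 480], 0.35)},
        "Pimelic acid": {"control": [5, 6, 9, 11, 13], "sigma": 0.6,
                         "test": _scaled([5, 6, 9, 11, 13], 0.55)},
        # SCFAs and lactic acid: maturation trend, no arm effect
        "Acetic acid": {"control": [9000, 11000, 14000, 16000, 18000], "sigma": 0.5},
        "Propionic acid": {"control": [1500, 2000, 3500, 4500, 5500], "sigma": 0.5},
        "Butyric acid": {"control": [400, 700, 1800, 2600, 3500], "sigma": 0.6},
        "Valeric acid": {"control": [50, 80, 200, 300, 400], "sigma": 0.6},
        "Lactic acid": {"control": [2500, 2000, 1000, 700, 500], "sigma": 0.6},
    }
    for entry in spec.values():
        entry.setdefault("test", list(entry["control"]))
    return spec


def _default_bile_acid_spec() -> dict:
    """Per-analyte log-normal locations for the 43-analyte bile-acid panel.

    In the control arm, unconjugated primaries (CA, CDCA) fall off with
    community maturation (declining deconjugation), while the test arm
    maintains them — the arm contrast behind the conjugation-ratio
    trajectories.  Conjugated pools are large and arm-independent.
    """
    spec = {
        "CA": {"control": [800, 550, 350, 250, 200],
               "test": [800, 780, 740, 700, 680], "sigma": 0.7},
        "CDCA": {"control": [480, 330, 210, 150, 120],
                 "test": [480, 470, 440, 420, 400], "sigma": 0.7},
        "DCA": {"control": [30, 50, 90, 130, 170], "sigma": 0.7},
        "LCA": {"control": [15, 20, 25, 30, 35], "sigma": 0.7},
        "GCA": {"control": [2000, 1900, 1700, 1600, 1500], "sigma": 0.6},
        "TCA": {"control": [1400, 1300, 1200, 1100, 1000], "sigma": 0.6},
        "GCDCA": {"control": [1500, 1400, 1300, 1200, 1100], "sigma": 0.6},
        "TCDCA": {"control": [900, 850, 800, 750, 700], "sigma": 0.6},
        "GDCA": {"control": [40, 55, 75, 95, 115], "sigma": 0.7},
        "TDCA": {"control": [25, 35, 50, 65, 80], "sigma": 0.7},
        "GLCA": {"control": [8, 10, 13, 16, 20], "sigma": 0.7},
        "TLCA": {"control": [6, 8, 10, 13, 16], "sigma": 0.7},
        "Dehydrocholic acid": {"control": [4, 5, 8, 10, 12], "sigma": 0.7,
                               "test": [2, 2.5, 4, 5, 6]},
    }
    # remaining analytes: flat trace levels, no arm effect
    for i, name in enumerate(BILE_ACID_PANEL):
        if name not in spec:
            level = 3.0 + 2.0 * (i % 12)
            spec[name] = {"control": [level] * 5, "sigma": 0.7}
    for entry in spec.values():
        entry.setdefault("test", list(entry["control"]))
    return spec


def _default_ko_spec() -> dict:
    """Per-KO abundance loadings across the five FCTs.

    Ehrlich-pathway enzymes (aminotransferases, 2-oxo acid decarboxylase,
    aldehyde dehydrogenases) rise with later FCTs; amine-pathway
    decarboxylases fall; choloylglycine hydrolase (BSH, K01442) peaks in
    the bifidobacteria-rich FCT2.
    """
    return {
        "K01442": [0.6, 1.6, 1.0, 0.8, 0.7],   # choloylglycine hydrolase (BSH)
        "K00826": [0.2, 0.4, 1.0, 1.5, 2.0],   # BCAA aminotransferase
        "K00832": [0.2, 0.4, 0.9, 1.4, 1.8],   # aromatic aminotransferase
        "K04073": [0.3, 0.4, 1.0, 1.4, 1.7],   # acetaldehyde dehydrogenase
        "K01593": [0.3, 0.5, 1.0, 1.3, 1.6],   # aromatic-L-AA decarboxylase
        "K00128": [0.4, 0.5, 1.0, 1.4, 1.8],   # aldehyde dehydrogenase (NAD+)
        "K00001": [0.5, 0.6, 1.0, 1.3, 1.6],   # alcohol dehydrogenase
        "K00161": [0.4, 0.5, 0.9, 1.2, 1.5],   # pyruvate dehydrogenase E1 alpha
        "K01580": [1.5, 1.2, 0.8, 0.6, 0.5],   # glutamate decarboxylase (amine)
        "K01581": [1.6, 1.3, 0.8, 0.6, 0.4],   # ornithine decarboxylase (amine)
        "K01582": [1.4, 1.2, 0.9, 0.7, 0.5],   # lysine decarboxylase (amine)
        "K00817": [0.5, 0.7, 1.0, 1.2, 1.4],   # histidinol-phosphate aminotransferase
        "K14260": [0.4, 0.6, 1.0, 1.3, 1.6],   # alanine-synthesizing transaminase
        "K00658": [0.5, 0.6, 0.9, 1.2, 1.4],   # 2-oxoglutarate dehydrogenase E2
        "K00382": [0.8, 0.9, 1.0, 1.1, 1.2],   # dihydrolipoyl dehydrogenase
        "K01667": [1.2, 1.0, 0.8, 0.7, 0.6],   # tryptophanase
        "K01754": [0.9, 0.9, 1.0, 1.0, 1.1],   # threonine ammonia-lyase
        "K00600": [1.0, 1.0, 1.0, 1.0, 1.0],   # glycine hydroxymethyltransferase
        "K00928": [1.0, 1.0, 1.0, 1.0, 1.0],   # aspartate kinase
        "K01714": [1.1, 1.0, 0.9, 0.9, 0.8],   # dihydrodipicolinate synthase
    }


@dataclass
class CohortConfig:
    """Generating parameters for a synthetic two-arm infant cohort."""

    n_infants: int = 130
    arm_ratio: float = 0.5
    enroll_age_range: tuple[int, int] = (14, 180)
    stratum_cutoff: int = 90
    n_fct: int = 5
    taxa: tuple[str, ...] = GENERA
    alpha_matrix: np.ndarray = field(default_factory=_default_alpha_matrix)
    base_hazards: tuple[float, ...] = (1 / 60, 1 / 90, 1 / 120, 1 / 150)
    treatment_hazard_ratio: float = 0.56
    depth_mean: float = 20000.0
    depth_dispersion: float = 10.0   # negative-binomial size parameter
    depth_floor: int = 2000
    metabolite_spec: dict = field(default_factory=_default_metabolite_spec)
    bile_acid_spec: dict = field(default_factory=_default_bile_acid_spec)
    ko_spec: dict = field(default_factory=_default_ko_spec)
    dropout_prob: float = 0.07
    seed: int = 0

    def validate(self) -> None:
        if self.n_fct < 2:
            raise ConfigError("n_fct must be >= 2")
        if not (0 < self.arm_ratio < 1):
            raise ConfigError("arm_ratio must be in (0, 1)")
        if self.treatment_hazard_ratio < 0:
            raise ConfigError("treatment_hazard_ratio must be >= 0")
        a = np.asarray(self.alpha_matrix, dtype=float)
        if a.shape != (self.n_fct, len(self.taxa)):
            raise ConfigError("alpha_matrix shape must be (n_fct, n_taxa)")
        if (a <= 0).any():
            raise ConfigError("alpha_matrix entries must be > 0")
        if len(self.base_hazards) != self.n_fct - 1:
            raise ConfigError("base_hazards must have n_fct - 1 entries")
        if any(h < 0 for h in self.base_hazards):
            raise ConfigError("base_hazards must be >= 0")
        if not (0 <= self.dropout_prob < 1):
            raise ConfigError("dropout_prob must be in [0, 1)")
        if self.enroll_age_range[0] < 0 or self.enroll_age_range[1] < self.enroll_age_range[0]:
            raise ConfigError("enroll_age_range must be a non-negative, ordered pair")
        for panel_name, panel in (("metabolite_spec", self.metabolite_spec),
                                  ("bile_acid_spec", self.bile_acid_spec)):
            for name, entry in panel.items():
                if entry["sigma"] <= 0:
                    raise ConfigError(f"{panel_name}[{name!r}]: sigma must be > 0")
                for arm in ("control", "test"):
                    if len(entry[arm]) != self.n_fct:
                        raise ConfigError(
                            f"{panel_name}[{name!r}][{arm}] needs {self.n_fct} locations")
                    if any(v <= 0 for v in entry[arm]):
                        raise ConfigError(f"{panel_name}[{name!r}]: locations must be > 0")

    def save(self, path) -> None:
        """Serialize scalar fields as flat TOML-style key = value lines."""
        lines = ["# cohort generator configuration"]
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float, str)):
                rep = f'"{v}"' if isinstance(v, str) else repr(v)
                lines.append(f"{f.name} = {rep}")
            elif isinstance(v, tuple) and all(isinstance(e, (int, float)) for e in v):
                lines.append(f"{f.name} = [{', '.join(repr(e) for e in v)}]")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")


def null_config(**overrides) -> CohortConfig:
    """Default configuration with all arm effects removed.

    Hazard ratio 1 and test-arm metabolite/bile-acid locations equal to the
    control arm's; useful for type-I-error calibration.
    """
    cfg = CohortConfig(**overrides)
    cfg.treatment_hazard_ratio = 1.0
    for panel in (cfg.metabolite_spec, cfg.bile_acid_spec):
        for entry in panel.values():
            entry["test"] = list(entry["control"])
    return cfg


def simulate_fct_trajectory(enroll_age: float, arm: str, config: CohortConfig,
                            seed: int | np.random.Generator) -> list[tuple[float, int]]:
    """Latent FCT trajectory: forward-only exponential jump process.

    Returns the full jump schedule [(age, fct), ...] starting at (0, FCT1);
    the state at any age is the last entry at or before it.  In the test arm
    every per-transition hazard is multiplied by the treatment hazard ratio.
    """
    if enroll_age < 0:
        raise ConfigError("enroll_age must be >= 0")
    if arm not in ("control", "test"):
        raise ConfigError(f"unknown arm {arm!r}")
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ratio = config.treatment_hazard_ratio if arm == "test" else 1.0
    traj = [(0.0, 1)]
    t = 0.0
    for stage, h in enumerate(config.base_hazards, start=1):
        rate = h * ratio
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        traj.append((t, stage + 1))
    return traj


def state_at(trajectory: list[tuple[float, int]], age: float) -> int:
    """Latent FCT at a given age from a jump schedule."""
    state = 1
    for t, fct in trajectory:
        if t <= age:
            state = fct
        else:
            break
    return state


def draw_genus_counts(fct_label: int, depth: int, config: CohortConfig,
                      seed: int | np.random.Generator) -> np.ndarray:
    """Dirichlet-multinomial genus counts for one sample."""
    config.validate()
    if not 1 <= fct_label <= config.n_fct:
        raise ConfigError(f"fct_label must be in 1..{config.n_fct}, got {fct_label}")
    if depth <= 0:
        raise ConfigError("depth must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = rng.dirichlet(np.asarray(config.alpha_matrix, dtype=float)[fct_label - 1])
    return rng.multinomial(depth, p)


def _draw_panel(spec: dict, fct_label: int, arm: str,
                rng: np.random.Generator) -> dict[str, float]:
    out = {}
    for name in spec:
        entry = spec[name]
        loc = entry[arm][fct_label - 1]
        out[name] = float(loc * np.exp(entry["sigma"] * rng.standard_normal()))
    return out


def draw_metabolome(fct_label: int, arm: str, config: CohortConfig,
                    seed: int | np.random.Generator) -> pd.Series:
    """One sample's metabolite panel (incl. the 43 bile-acid analytes), nmol/g."""
    config.validate()
    if not 1 <= fct_label <= config.n_fct:
        raise ConfigError(f"fct_label must be in 1..{config.n_fct}, got {fct_label}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = _draw_panel(config.metabolite_spec, fct_label, arm, rng)
    ba = _draw_panel(config.bile_acid_spec, fct_label, arm, rng)
    # bile-acid analytes shared with the general panel keep the BA draw
    vals.update(ba)
    return pd.Series(vals, dtype=float)


def draw_ko(fct_label: int, config: CohortConfig,
            seed: int | np.random.Generator) -> pd.Series:
    """KO relative abundances: FCT loadings x log-normal noise, normalized."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = {}
    for ko, loadings in config.ko_spec.items():
        vals[ko] = loadings[fct_label - 1] * np.exp(0.5 * rng.standard_normal())
    s = pd.Series(vals, dtype=float)
    return s / s.sum()


@dataclass
class SyntheticCohort:
    """Generated cohort: aligned metadata, counts, metabolites, KOs, truth."""

    metadata: SampleTable
    counts: TaxaCountMatrix
    metabolites: MetaboliteMatrix
    ko: KOAbundanceMatrix
    truth_fct: pd.Series
    truth_params: CohortConfig

    def write_tables(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.metadata.to_tsv(out / "metadata.tsv")
        self.counts.to_tsv(out / "genus_counts.tsv")
        self.metabolites.to_tsv(out / "metabolites.tsv")
        self.ko.to_tsv(out / "ko_abundance.tsv")
        self.truth_fct.rename("truth_fct").rename_axis("sample_id").reset_index() \
            .to_csv(out / "truth_fct.tsv", sep="\t", index=False)
        self.truth_params.save(out / "config.toml")


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Generate a complete synthetic cohort, deterministic for a fixed seed.

    Visit schedule per infant: V0 at enrollment, V1 thirty days later, V3
    ninety days later, V6 at 365 days of age.  V0 is always collected; each
    later visit is independently dropped with ``dropout_prob``.
    """
    config = config or CohortConfig()
    config.validate()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    n = config.n_infants
    n_test = int(round(n * config.arm_ratio))
    arms = np.array(["test"] * n_test + ["control"] * (n - n_test))
    rng.shuffle(arms)

    lo, hi = config.enroll_age_range
    enroll_ages = rng.integers(lo, hi + 1, size=n)

    meta_rows = []
    count_rows, mtb_rows, ko_rows, truth = {}, {}, {}, {}
    for i in range(n):
        iid = f"I{i + 1:03d}"
        arm = str(arms[i])
        e_age = int(enroll_ages[i])
        stratum = assign_cohort(e_age)
        traj = simulate_fct_trajectory(e_age, arm, config, rng)
        schedule = {"V0": e_age, "V1": e_age + 30, "V3": e_age + 90, "V6": 365}
        for visit in ("V0", "V1", "V3", "V6"):
            dropped = visit != "V0" and rng.random() < config.dropout_prob
            if dropped:
                continue
            age = schedule[visit]
            fct = state_at(traj, age)
            depth = max(int(rng.negative_binomial(
                config.depth_dispersion,
                config.depth_dispersion / (config.depth_dispersion + config.depth_mean))),
                config.depth_floor)
            sid = f"{iid}_{visit}"
            meta_rows.append({"sample_id": sid, "infant_id": iid, "visit": visit,
                              "age": age, "arm": arm, "stratum": stratum})
            count_rows[sid] = draw_genus_counts(fct, depth, config, rng)
            mtb_rows[sid] = draw_metabolome(fct, arm, config, rng)
            ko_rows[sid] = draw_ko(fct, config, rng)
            truth[sid] = fct

    metadata = SampleTable(pd.DataFrame(meta_rows))
    counts = TaxaCountMatrix(
        pd.DataFrame.from_dict(count_rows, orient="index", columns=list(config.taxa)),
        level="genus",
    )
    metabolites = MetaboliteMatrix(pd.DataFrame.from_dict(mtb_rows, orient="index"))
    ko = KOAbundanceMatrix(pd.DataFrame.from_dict(ko_rows, orient="index"))
    return SyntheticCohort(metadata=metadata, counts=counts, metabolites=metabolites,
                           ko=ko, truth_fct=pd.Series(truth, name="truth_fct"),
                           truth_params=config)
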