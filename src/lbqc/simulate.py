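"""Truth-labelled synthetic 16S cohorts for exercising the QC and
decontamination pipeline.

The generator emulates the statistical structure of a plate-based,
low-biomass amplicon experiment:

* nasopharyngeal-like specimens whose total bacterial biomass (16S copies/μl)
  rises with participant age, sequenced as within- or between-run technical
  repeats;
* no-template controls (NTCs) carrying only the storage buffer's reagent
  background;
* mock-community extraction controls at two biomass levels, the low level a
  1-in-10^4 dilution of the high;
* buffer-specific reagent contamination that displaces true signal as
  biomass falls, mixed as w = B/(B+κ) true signal and 1−w background;
* DNA-extraction-kit lysis bias against gram-positive taxa;
* plate-local well-to-well spill-over, donated preferentially by
  high-biomass wells;
* spurious rare OTUs whose per-sample rate decreases with biomass.

Every OTU carries a ground-truth origin label so classifier performance can
be scored exactly.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    Buffer,
    CountTable,
    Kit,
    MockReference,
    Role,
    SampleRecord,
    TaxonomyMap,
)

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "contamination_weight",
    "apply_kit_bias",
    "builtin_mock",
    "generate_cohort",
    "score_classifier",
]


# ---------------------------------------------------------------------------
# Taxon pools

# (genus, species, gram class) for plausible upper-respiratory organisms.
TRUE_TAXON_POOL: list[tuple[str, str, str]] = [
    ("Moraxella", "catarrhalis", "gram_negative"),
    ("Moraxella", "nonliquefaciens", "gram_negative"),
    ("Moraxella", "lincolnii", "gram_negative"),
    ("Corynebacterium", "propinquum", "gram_positive"),
    ("Corynebacterium", "pseudodiphtheriticum", "gram_positive"),
    ("Corynebacterium", "accolens", "gram_positive"),
    ("Haemophilus", "influenzae", "gram_negative"),
    ("Haemophilus", "parainfluenzae", "gram_negative"),
    ("Haemophilus", "haemolyticus", "gram_negative"),
    ("Streptococcus", "pneumoniae", "gram_positive"),
    ("Streptococcus", "mitis", "gram_positive"),
    ("Streptococcus", "salivarius", "gram_positive"),
    ("Streptococcus", "anginosus", "gram_positive"),
    ("Staphylococcus", "aureus", "gram_positive"),
    ("Staphylococcus", "epidermidis", "gram_positive"),
    ("Staphylococcus", "hominis", "gram_positive"),
    ("Dolosigranulum", "pigrum", "gram_positive"),
    ("Neisseria", "lactamica", "gram_negative"),
    ("Neisseria", "meningitidis", "gram_negative"),
    ("Prevotella", "melaninogenica", "gram_negative"),
    ("Prevotella", "nanceiensis", "gram_negative"),
    ("Veillonella", "dispar", "gram_negative"),
    ("Veillonella", "atypica", "gram_negative"),
    ("Gemella", "haemolysans", "gram_positive"),
    ("Rothia", "mucilaginosa", "gram_positive"),
    ("Granulicatella", "adiacens", "gram_positive"),
    ("Fusobacterium", "nucleatum", "gram_negative"),
    ("Leptotrichia", "unclassified", "gram_negative"),
    ("Porphyromonas", "unclassified", "gram_negative"),
    ("Actinomyces", "unclassified", "gram_positive"),
    ("Lactobacillus", "iners", "gram_positive"),
    ("Lactobacillus", "gasseri", "gram_positive"),
    ("Alloiococcus", "otitis", "gram_positive"),
    ("Turicella", "otitidis", "gram_positive"),
    ("Klebsiella", "pneumoniae", "gram_negative"),
    ("Acinetobacter", "baumannii", "gram_negative"),
    ("Enterobacter", "unclassified", "gram_negative"),
    ("Micrococcus", "luteus", "gram_positive"),
    ("Abiotrophia", "defectiva", "gram_positive"),
    ("Bergeyella", "unclassified", "gram_negative"),
]

# Genera repeatedly reported from extraction/PCR reagents ("kitome").
CONTAMINANT_TAXON_POOL: list[tuple[str, str, str]] = [
    ("Ralstonia", "pickettii", "gram_negative"),
    ("Sphingomonas", "unclassified", "gram_negative"),
    ("Methylobacterium", "unclassified", "gram_negative"),
    ("Bradyrhizobium", "unclassified", "gram_negative"),
    ("Burkholderia", "unclassified", "gram_negative"),
    ("Delftia", "acidovorans", "gram_negative"),
    ("Acidovorax", "unclassified", "gram_negative"),
    ("Pelomonas", "unclassified", "gram_negative"),
    ("Cupriavidus", "unclassified", "gram_negative"),
    ("Herbaspirillum", "unclassified", "gram_negative"),
    ("Mesorhizobium", "unclassified", "gram_negative"),
    ("Phyllobacterium", "unclassified", "gram_negative"),
    ("Aquabacterium", "unclassified", "gram_negative"),
    ("Caulobacter", "unclassified", "gram_negative"),
    ("Novosphingobium", "unclassified", "gram_negative"),
    ("Brevundimonas", "diminuta", "gram_negative"),
    ("Stenotrophomonas", "maltophilia", "gram_negative"),
    ("Comamonas", "unclassified", "gram_negative"),
    ("Variovorax", "paradoxus", "gram_negative"),
    ("Afipia", "unclassified", "gram_negative"),
]

# Cluster-defining dominant genera (dominance structure of infant
# nasopharyngeal profiles).
CLUSTER_GENERA = [
    "Moraxella",
    "Corynebacterium",
    "Haemophilus",
    "Streptococcus",
    "Staphylococcus",
    "Dolosigranulum",
]

_ZYMO = {
    ("Pseudomonas", "aeruginosa", "gram_negative"): 0.046,
    ("Escherichia", "coli", "gram_negative"): 0.100,
    ("Salmonella", "enterica", "gram_negative"): 0.113,
    ("Lactobacillus", "fermentum", "gram_positive"): 0.188,
    ("Enterococcus", "faecalis", "gram_positive"): 0.104,
    ("Staphylococcus", "aureus", "gram_positive"): 0.133,
    ("Listeria", "monocytogenes", "gram_positive"): 0.159,
    ("Bacillus", "subtilis", "gram_positive"): 0.157,
}

# HM-783D staggered genomic-DNA standard: manufacturer proportions, which
# sum to 0.9988 as stated; renormalized here so the composition closes to 1.
_BEI_RAW = {
    "Pseudomonas aeruginosa": 2.2,
    "Escherichia coli": 21.9,
    "Rhodobacter sphaeroides": 21.9,
    "Clostridium beijerinckii": 2.2,
    "Streptococcus agalactiae/mutans/pneumoniae": 24.1,
    "Staphylococcus aureus/epidermidis": 24.1,
    "Bacillus cereus": 2.2,
    "Acinetobacter baumannii": 0.2,
    "Neisseria meningitidis": 0.2,
    "Lactobacillus gasseri": 0.2,
    "Listeria monocytogenes": 0.2,
    "Helicobacter pylori": 0.2,
    "Propionibacterium acnes": 0.2,
    "Enterococcus faecalis": 0.02,
    "Bacteroides vulgatus": 0.02,
    "Actinomyces odontolyticus": 0.02,
    "Deinococcus radiodurans": 0.02,
}


def builtin_mock(name: str) -> MockReference:
    """Return a bundled mock-community reference composition.

    ``zymobiomics``: the even 8-member cell standard; ``bei``: the 17-member
    staggered genomic-DNA standard.
    """
    if name == "zymobiomics":
        comp = {f"{g} {s}": p for (g, s, _), p in _ZYMO.items()}
        return MockReference("zymobiomics", comp)
    if name == "bei":
        total = sum(_BEI_RAW.values())
        return MockReference("bei", {k: v / total for k, v in _BEI_RAW.items()})
    raise ValueError(f"unknown mock standard {name!r}; options: zymobiomics, bei")


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class SimConfig:
    """Generative parameters of the synthetic cohort.

    Defaults describe the study conditions the package is validated under:
    ~120 repeat columns from ``n_specimens`` underlying specimens of which
    roughly 100 pass the 500 copies/μl gate, 10 NTCs, and 24 mock-community
    controls (3 replicates per kit x buffer combination at each of two
    biomass levels). ``kappa_*`` are the buffer reagent pseudo-biomasses
    (copies/μl equivalents) calibrated so that diluted mocks show ~9.5%
    (STGG) and ~1.5% (Primestore) background.
    """

    n_specimens: int = 56
    n_ntc: int = 10
    n_mock_high: int = 12
    n_mock_low: int = 12
    dilution_factor: float = 1e4
    n_true_taxa: int = 40
    n_contaminant_taxa: int = 20

    # contamination mixture
    kappa_primestore: float = 3.05
    kappa_stgg: float = 21.0
    # additional contaminant pseudo-biomass seen only by biological
    # specimens (collection swab/matrix background on top of the reagent
    # background); NTCs and mocks carry the buffer term alone
    kappa_specimen: float = 60.0
    mock_high_biomass: float = 2e6
    # Dirichlet concentration of the per-library reagent realization around
    # the buffer's base profile (lot-to-lot/aliquot variability)
    contaminant_concentration: float = 25.0

    # plate effects
    spillover_rate: float = 0.002
    kit_bias: dict = field(
        default_factory=lambda: {
            "kit_qs": {"gram_positive": 0.85},
            "kit_zb": {"gram_positive": 0.5},
        }
    )

    # sequencing depth (lognormal)
    mean_reads: float = 9000.0
    depth_sigma: float = 0.6

    # spurious OTUs: per-sample Poisson rate λ0·(B+1)^(−exponent)
    spurious_rate: float = 4.0
    spurious_exponent: float = 0.15

    # biomass vs age: ln B = β0 + β1·ln(age_days+1) + N(0, σ)
    age_beta0: float = 4.5
    age_beta1: float = 1.0
    age_sigma: float = 1.5
    # age draw: early-life mass at U(0,14) days, else lognormal
    early_life_fraction: float = 0.25
    age_log_median: float = math.log(90.0)
    age_log_sigma: float = 0.9

    # technical repeat design (remainder of specimens sequenced once)
    frac_duplicate: float = 0.50
    frac_triplicate: float = 0.25
    frac_quadruplicate: float = 0.10
    within_run_fraction: float = 0.4
    n_runs: int = 4

    # qPCR-like measurement noise on copies/μl
    copies_noise_sigma: float = 0.2

    # specimen composition: Dirichlet(base_alpha + cluster_boost on the
    # dominant genus' taxa); small base_alpha gives the strong single-genus
    # dominance typical of infant nasopharyngeal profiles
    base_alpha: float = 0.04
    cluster_boost: float = 15.0

    seed: int = 0

    def validate(self) -> None:
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must be > 1")
        for name in ("kappa_primestore", "kappa_stgg", "kappa_specimen"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.spillover_rate < 1):
            raise ValueError("spillover_rate must be in [0, 1)")
        fr = self.frac_duplicate + self.frac_triplicate + self.frac_quadruplicate
        if fr > 1 + 1e-12:
            raise ValueError("repeat fractions sum to more than 1")
        if not (0 <= self.within_run_fraction <= 1):
            raise ValueError("within_run_fraction must be in [0, 1]")
        if not (0 <= self.early_life_fraction <= 1):
            raise ValueError("early_life_fraction must be in [0, 1]")
        for name in ("n_specimens", "n_ntc", "n_mock_high", "n_mock_low", "n_runs"):
            if getattr(self, name) < 0 or (name == "n_runs" and self.n_runs < 1):
                raise ValueError(f"invalid {name}")
        for kit, biases in self.kit_bias.items():
            for cls, b in biases.items():
                if not (0 < b <= 1):
                    raise ValueError(
                        f"kit_bias[{kit}][{cls}] must lie in (0, 1], got {b}"
                    )
        if self.spurious_rate < 0 or self.spurious_exponent < 0:
            raise ValueError("spurious model parameters must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth for a generated cohort.

    ``otu_origin`` partitions the OTU set into ``true_taxon`` (respiratory
    pool), ``reagent_contaminant`` (buffer background pool), ``spillover``
    (mock-community taxa, which reach specimen/NTC wells only through
    well-to-well transfer) and ``spurious``. ``samples`` holds per-column
    scalars (true biomass B, mixing weight w, realized spill-over fraction,
    cluster, repeat group). ``expected_profile`` is the noiseless per-column
    composition the reads were drawn from, over the non-spurious OTUs.
    """

    otu_origin: dict[str, str]
    samples: pd.DataFrame
    true_composition: pd.DataFrame
    expected_profile: pd.DataFrame

    def origins(self, origin: str) -> list[str]:
        return [o for o, lab in self.otu_origin.items() if lab == origin]


# ---------------------------------------------------------------------------
# Elementary model pieces


def contamination_weight(biomass: float, kappa: float) -> float:
    """Mixing weight of true signal, w = B/(B+κ).

    The expected contaminant read share is 1−w: reagent background carries a
    fixed pseudo-biomass κ, so it dominates as specimen biomass falls.
    """
    if biomass < 0 or kappa < 0:
        raise ValueError("biomass and kappa must be non-negative")
    if biomass == 0 and kappa == 0:
        raise ValueError("mixture undefined for biomass = kappa = 0")
    return biomass / (biomass + kappa)


def apply_kit_bias(
    composition: np.ndarray | Sequence[float],
    multipliers: np.ndarray | Sequence[float],
) -> np.ndarray:
    """Reweight a composition by per-taxon lysis efficiencies and re-close.

    p'_j = b_j p_j / Σ_k b_k p_k with b_j in (0, 1].
    """
    p = np.asarray(composition, dtype=float)
    b = np.asarray(multipliers, dtype=float)
    if p.shape != b.shape:
        raise ValueError("composition and multipliers must have equal length")
    if (b <= 0).any() or (b > 1).any():
        raise ValueError("multipliers must lie in (0, 1]")
    out = b * p
    total = out.sum()
    if total <= 0:
        raise ValueError("composition vanished after biasing")
    return out / total


def _substream(seed: int, tag: int, key: str = "") -> np.random.Generator:
    """Per-entity RNG keyed by a stable hash so draws for one sample do not
    depend on cohort size or ordering."""
    return np.random.default_rng(
        [int(seed) & 0x7FFFFFFF, tag, zlib.crc32(key.encode("utf-8"))]
    )


# ---------------------------------------------------------------------------
# Cohort generation

_MOCK_DESIGNS = [
    (Buffer.PRIMESTORE, Kit.KIT_QS),
    (Buffer.PRIMESTORE, Kit.KIT_ZB),
    (Buffer.STGG, Kit.KIT_QS),
    (Buffer.STGG, Kit.KIT_ZB),
]


@dataclass
class _Column:
    sample_id: str
    role: Role
    buffer: Buffer
    kit: Kit
    biomass: float
    age_days: float
    repeat_group: str | None
    run: str
    cluster: str
    true_comp: np.ndarray | None  # over core OTUs, sums to 1 (or None for NTC)
    eps: float
    depth: int


def _taxon_table(cfg: SimConfig):
    """Core OTU ids, taxonomy, gram classes and origin labels."""
    if cfg.n_true_taxa > len(TRUE_TAXON_POOL):
        raise ValueError("n_true_taxa exceeds the built-in pool")
    if cfg.n_contaminant_taxa > len(CONTAMINANT_TAXON_POOL):
        raise ValueError("n_contaminant_taxa exceeds the built-in pool")
    otus: list[str] = []
    tax: TaxonomyMap = {}
    gram: dict[str, str] = {}
    origin: dict[str, str] = {}
    for i, (g, s, cls) in enumerate(TRUE_TAXON_POOL[: cfg.n_true_taxa]):
        oid = f"OTU_T{i + 1:03d}"
        otus.append(oid)
        tax[oid] = (g, s)
        gram[oid] = cls
        origin[oid] = "true_taxon"
    for i, ((g, s, cls), _p) in enumerate(_ZYMO.items()):
        oid = f"OTU_M{i + 1:03d}"
        otus.append(oid)
        tax[oid] = (g, s)
        gram[oid] = cls
        origin[oid] = "spillover"
    for i, (g, s, cls) in enumerate(CONTAMINANT_TAXON_POOL[: cfg.n_contaminant_taxa]):
        oid = f"OTU_C{i + 1:03d}"
        otus.append(oid)
        tax[oid] = (g, s)
        gram[oid] = cls
        origin[oid] = "reagent_contaminant"
    return otus, tax, gram, origin


def _kit_multipliers(cfg: SimConfig, kit: Kit, gram: Sequence[str]) -> np.ndarray:
    biases = cfg.kit_bias.get(kit.value, {})
    return np.array([biases.get(cls, 1.0) for cls in gram])


def generate_cohort(
    cfg: SimConfig,
) -> tuple[CountTable, list[SampleRecord], TaxonomyMap, SyntheticTruth]:
    """Generate one synthetic experiment; bit-reproducible for a fixed seed."""
    cfg.validate()
    seed = cfg.seed
    otus, tax, gram_map, origin = _taxon_table(cfg)
    n_core = len(otus)
    otu_index = {o: i for i, o in enumerate(otus)}
    true_idx = [otu_index[o] for o, lab in origin.items() if lab == "true_taxon"]
    mock_idx = [otu_index[o] for o, lab in origin.items() if lab == "spillover"]
    contam_idx = [
        otu_index[o] for o, lab in origin.items() if lab == "reagent_contaminant"
    ]
    gram = [gram_map[o] for o in otus]

    cohort_rng = _substream(seed, 0)
    # buffer-level base reagent profiles over the contaminant taxa
    base_contam = {
        Buffer.PRIMESTORE: cohort_rng.dirichlet(np.ones(len(contam_idx))),
        Buffer.STGG: cohort_rng.dirichlet(np.ones(len(contam_idx))),
    }

    # cluster Dirichlet concentrations over the true taxa
    cluster_alpha: dict[str, np.ndarray] = {}
    for genus in CLUSTER_GENERA:
        a = np.full(len(true_idx), cfg.base_alpha)
        members = [
            k for k, i in enumerate(true_idx) if tax[otus[i]][0] == genus
        ]
        if members:
            a[members] += cfg.cluster_boost / len(members)
        cluster_alpha[genus] = a

    mock_comp = np.zeros(len(mock_idx))
    for i, ((g, s, _cls), p) in enumerate(_ZYMO.items()):
        mock_comp[i] = p
    mock_comp /= mock_comp.sum()

    kappa = {
        Buffer.PRIMESTORE: cfg.kappa_primestore,
        Buffer.STGG: cfg.kappa_stgg,
    }
    runs = [f"run{r + 1}" for r in range(cfg.n_runs)]
    columns: list[_Column] = []

    # --- specimens with technical repeats -------------------------------
    cum = np.cumsum(
        [cfg.frac_duplicate, cfg.frac_triplicate, cfg.frac_quadruplicate]
    )
    for g in range(cfg.n_specimens):
        group = f"G{g + 1:03d}"
        grng = _substream(seed, 2, group)
        u_age = grng.random()
        if u_age < cfg.early_life_fraction:
            age = grng.uniform(0.0, 14.0)
        else:
            age = float(
                np.exp(grng.normal(cfg.age_log_median, cfg.age_log_sigma))
            )
        biomass = float(
            np.exp(
                cfg.age_beta0
                + cfg.age_beta1 * math.log(age + 1.0)
                + grng.normal(0.0, cfg.age_sigma)
            )
        )
        cluster = CLUSTER_GENERA[grng.integers(len(CLUSTER_GENERA))]
        comp_true = grng.dirichlet(cluster_alpha[cluster])
        u = grng.random()
        k = 2 if u < cum[0] else 3 if u < cum[1] else 4 if u < cum[2] else 1
        within = grng.random() < cfg.within_run_fraction
        start_run = int(grng.integers(cfg.n_runs))
        shared_eps = float(cfg.spillover_rate * grng.gamma(2.0, 0.5))
        shared_depth = int(
            round(np.exp(grng.normal(math.log(cfg.mean_reads), cfg.depth_sigma)))
        )
        true_comp = np.zeros(n_core)
        for j, i in enumerate(true_idx):
            true_comp[i] = comp_true[j]
        for rep in range(k):
            sid = f"SP{g + 1:03d}_r{rep + 1}"
            run = runs[start_run] if (within or k == 1) else runs[
                (start_run + rep) % cfg.n_runs
            ]
            if within and k > 1:
                eps, depth = shared_eps, shared_depth
            else:
                crng = _substream(seed, 3, sid)
                eps = float(cfg.spillover_rate * crng.gamma(2.0, 0.5))
                depth = int(
                    round(
                        np.exp(
                            crng.normal(math.log(cfg.mean_reads), cfg.depth_sigma)
                        )
                    )
                )
            columns.append(
                _Column(
                    sid,
                    Role.SPECIMEN,
                    Buffer.PRIMESTORE,
                    Kit.KIT_QS,
                    biomass,
                    age,
                    group if k > 1 else group,
                    run,
                    cluster,
                    true_comp,
                    max(eps, 0.0),
                    max(depth, 100),
                )
            )

    # --- NTCs ------------------------------------------------------------
    for i in range(cfg.n_ntc):
        sid = f"NTC{i + 1:02d}"
        crng = _substream(seed, 3, sid)
        eps = float(cfg.spillover_rate * crng.gamma(2.0, 0.5))
        depth = int(
            round(np.exp(crng.normal(math.log(cfg.mean_reads), cfg.depth_sigma)))
        )
        columns.append(
            _Column(
                sid,
                Role.NTC,
                Buffer.PRIMESTORE,
                Kit.KIT_QS,
                0.0,
                float("nan"),
                None,
                runs[i % cfg.n_runs],
                "",
                None,
                max(eps, 0.0),
                max(depth, 100),
            )
        )

    # --- mock communities -------------------------------------------------
    mock_true = np.zeros(n_core)
    for j, i in enumerate(mock_idx):
        mock_true[i] = mock_comp[j]
    for level, count, bmass in (
        ("H", cfg.n_mock_high, cfg.mock_high_biomass),
        ("L", cfg.n_mock_low, cfg.mock_high_biomass / cfg.dilution_factor),
    ):
        for i in range(count):
            buffer, kit = _MOCK_DESIGNS[i % len(_MOCK_DESIGNS)]
            sid = f"MOCK{level}{i + 1:02d}"
            crng = _substream(seed, 3, sid)
            eps = float(cfg.spillover_rate * crng.gamma(2.0, 0.5))
            depth = int(
                round(
                    np.exp(crng.normal(math.log(cfg.mean_reads), cfg.depth_sigma))
                )
            )
            columns.append(
                _Column(
                    sid,
                    Role.MOCK,
                    buffer,
                    kit,
                    bmass,
                    float("nan"),
                    None,
                    runs[i % cfg.n_runs],
                    "",
                    mock_true,
                    max(eps, 0.0),
                    max(depth, 100),
                )
            )

    if not columns:
        raise ValueError("configuration generates no samples")

    # --- intrinsic expected profiles --------------------------------------
    intrinsic = np.zeros((n_core, len(columns)))
    weights = np.zeros(len(columns))
    for j, col in enumerate(columns):
        crng = _substream(seed, 4, col.sample_id)
        kap = kappa[col.buffer]
        if col.role == Role.SPECIMEN:
            kap += cfg.kappa_specimen
        w = contamination_weight(col.biomass, kap) if (col.biomass or kap) else 1.0
        weights[j] = w
        contam_real = crng.dirichlet(
            cfg.contaminant_concentration * base_contam[col.buffer]
            + 1e-9  # guard against zero concentrations
        )
        profile = np.zeros(n_core)
        if col.true_comp is not None and w > 0:
            mult = _kit_multipliers(cfg, col.kit, gram)
            profile += w * apply_kit_bias(col.true_comp, mult)
        profile_c = np.zeros(n_core)
        for jj, i in enumerate(contam_idx):
            profile_c[i] = contam_real[jj]
        profile += (1.0 - w) * profile_c
        intrinsic[:, j] = profile

    # --- plate-local spill-over -------------------------------------------
    # one 96-well plate per run (overflow opens further plates)
    plate_of: list[tuple[str, int]] = []
    well_of: list[str] = []
    per_run_counter: dict[str, int] = {}
    for col in columns:
        i = per_run_counter.get(col.run, 0)
        per_run_counter[col.run] = i + 1
        plate_of.append((col.run, i // 96))
        pos = i % 96
        well_of.append(f"{chr(65 + pos // 12)}{pos % 12 + 1}")

    final = np.zeros_like(intrinsic)
    spill_frac = np.zeros(len(columns))
    biomasses = np.array([c.biomass for c in columns])
    for plate in sorted(set(plate_of)):
        members = [j for j, p in enumerate(plate_of) if p == plate]
        sub_b = biomasses[members]
        for j in members:
            others = [m for m in members if m != j]
            eps = columns[j].eps
            donor_b = biomasses[others] if others else np.array([])
            if others and donor_b.sum() > 0 and eps > 0:
                w_d = donor_b / donor_b.sum()
                spill = intrinsic[:, others] @ w_d
                final[:, j] = (intrinsic[:, j] + eps * spill) / (1.0 + eps)
                spill_frac[j] = eps / (1.0 + eps)
            else:
                final[:, j] = intrinsic[:, j]
                spill_frac[j] = 0.0

    # --- read sampling -----------------------------------------------------
    counts = np.zeros((n_core, len(columns)), dtype=np.int64)
    measured = np.zeros(len(columns))
    for j, col in enumerate(columns):
        crng = _substream(seed, 5, col.sample_id)
        p = final[:, j]
        s = p.sum()
        if s <= 0:
            continue
        counts[:, j] = crng.multinomial(col.depth, p / s)
        if col.biomass > 0:
            measured[j] = col.biomass * float(
                np.exp(crng.normal(0.0, cfg.copies_noise_sigma))
            )

    # --- spurious OTUs ------------------------------------------------------
    spur_ids: list[str] = []
    spur_entries: list[tuple[str, int, int]] = []  # (otu, column index, count)
    for j, col in enumerate(columns):
        crng = _substream(seed, 6, col.sample_id)
        lam = cfg.spurious_rate * (col.biomass + 1.0) ** (-cfg.spurious_exponent)
        n_sp = int(crng.poisson(lam))
        for k in range(n_sp):
            oid = f"OTU_S{j + 1:03d}_{k + 1}"
            spur_ids.append(oid)
            c = 1 + int(crng.random() < 0.3)
            spur_entries.append((oid, j, c))
            if len(columns) > 1 and crng.random() < 0.1:
                partner = (j + 1) % len(columns)
                spur_entries.append((oid, partner, 1))

    all_otus = otus + spur_ids
    full = np.zeros((len(all_otus), len(columns)), dtype=np.int64)
    full[:n_core, :] = counts
    spur_pos = {o: n_core + i for i, o in enumerate(spur_ids)}
    for oid, j, c in spur_entries:
        full[spur_pos[oid], j] += c

    sample_ids = [c.sample_id for c in columns]
    table = CountTable(pd.DataFrame(full, index=all_otus, columns=sample_ids))

    records = [
        SampleRecord(
            sample_id=c.sample_id,
            role=c.role,
            copies_per_ul=float(measured[j]),
            age_days=c.age_days,
            run_id=c.run,
            well=well_of[j],
            repeat_group=c.repeat_group if c.role == Role.SPECIMEN else None,
            buffer=c.buffer,
            kit=c.kit,
        )
        for j, c in enumerate(columns)
    ]

    full_tax = dict(tax)
    for oid in spur_ids:
        full_tax[oid] = ("unclassified", "unclassified")

    full_origin = dict(origin)
    for oid in spur_ids:
        full_origin[oid] = "spurious"

    samples_df = pd.DataFrame(
        {
            "role": [c.role.value for c in columns],
            "true_biomass": [c.biomass for c in columns],
            "mixing_weight": weights,
            "spillover_fraction": spill_frac,
            "cluster": [c.cluster for c in columns],
            "repeat_group": [c.repeat_group or "" for c in columns],
            "run_id": [c.run for c in columns],
            "depth": [c.depth for c in columns],
        },
        index=sample_ids,
    )
    truth = SyntheticTruth(
        otu_origin=full_origin,
        samples=samples_df,
        true_composition=pd.DataFrame(
            np.column_stack(
                [
                    c.true_comp if c.true_comp is not None else np.zeros(n_core)
                    for c in columns
                ]
            ),
            index=otus,
            columns=sample_ids,
        ),
        expected_profile=pd.DataFrame(final, index=otus, columns=sample_ids),
    )
    return table, records, full_tax, truth


def score_classifier(
    contaminant_ids: Sequence[str],
    truth: SyntheticTruth,
    counts: CountTable,
    records: Sequence[SampleRecord],
) -> dict[str, float]:
    """Sensitivity and false-positive rate of contaminant calls.

    Both rates are computed over OTUs detected in at least one specimen
    column of ``counts`` — an OTU absent from every specimen can neither be
    removed from them nor corrupt them. Sensitivity is the flagged fraction
    of reagent-contaminant OTUs; the false-positive rate is the flagged
    fraction of genuine (true_taxon) OTUs.
    """
    spec_ids = [
        r.sample_id
        for r in records
        if r.role == Role.SPECIMEN and r.sample_id in counts.sample_ids
    ]
    in_spec = (counts.data[spec_ids] > 0).any(axis=1)
    flagged = set(contaminant_ids)
    present = set(counts.otu_ids)

    def eligible(origin: str) -> list[str]:
        return [
            o
            for o in truth.origins(origin)
            if o in present and bool(in_spec[o])
        ]

    contam = eligible("reagent_contaminant")
    genuine = eligible("true_taxon")
    return {
        "sensitivity": len(flagged & set(contam)) / len(contam)
        if contam
        else float("nan"),
        "false_positive_rate": len(flagged & set(genuine)) / len(genuine)
        if genuine
        else float("nan"),
        "n_contaminant_otus": float(len(contam)),
        "n_true_otus": float(len(genuine)),
    }
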