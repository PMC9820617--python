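"""Synthetic TCGA-like glioma cohorts with planted class structure.

Generation is truth-first: each case first draws a latent WHO CNS5 class
(oligodendroglioma IDH-mut codeleted, astrocytoma IDH-mut grade 2-4,
glioblastoma IDH-wt, or a pediatric-type H3-mutant exit), conditioned on its
legacy histology; the observable molecular fields are then generated to be
consistent with that truth, so the rule engine recovers the latent class
exactly whenever no field is masked. Missingness is applied afterwards,
field by field.

The default cohort composition mirrors the legacy TCGA histology counts
(174 oligodendrogliomas, 114 oligoastrocytomas, 169 astrocytomas, 590
glioblastomas, 75 unknown-histology cases) and the default per-class median
overall survivals mirror the published group medians; everything is
configurable through :class:`SimConfig`. Expression and methylation carry
class-specific mean-shifted gene blocks (plus planted subtype-signature
blocks, biomarker genes and a toy FREM2-like pathway hierarchy) on top of a
log-normal baseline; survival is exponential per class with Bernoulli
censoring. All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CaseAnnotation, ExpressionMatrix, MethylationMatrix
from .mutations import MafRecord
from .pal import PathwayDefinition
from .subtypes import SUBTYPE_NAMES, SubtypeSignature
from . import rules as R

__all__ = [
    "SimConfig",
    "simulate_cohort",
    "simulate_expression",
    "simulate_methylation",
    "simulate_survival",
    "simulate_maf",
    "toy_frem2_pathways",
]

# Latent truth classes used by the simulator (category, grade)
_CLASSES = {
    "oligo2": (R.OLIGO, 2),
    "oligo3": (R.OLIGO, 3),
    "astro2": (R.ASTRO, 2),
    "astro3": (R.ASTRO, 3),
    "astro4": (R.ASTRO, 4),
    "gbm": (R.GBM, 4),
    "ped_k27": (R.PED_K27, None),
    "ped_g34": (R.PED_G34, None),
    "excluded": (R.EXCLUDED, None),
}


def _default_truth_mix() -> dict[str, dict[str, float]]:
    # P(latent CNS5 family | legacy histology); lower-grade families split
    # into grade 2/3 by grade3_fraction at draw time.
    return {
        "oligodendroglioma": {"oligo": 0.90, "astro": 0.06, "gbm": 0.04},
        "oligoastrocytoma": {"oligo": 0.35, "astro": 0.45, "gbm": 0.20},
        "astrocytoma": {"astro": 0.52, "gbm": 0.46, "ped_k27": 0.01, "ped_g34": 0.01},
        "glioblastoma": {"gbm": 0.92, "astro4": 0.08},
    }


def _default_missingness() -> dict[str, float]:
    return {
        "idh_status": 0.10,
        "h3_status": 0.15,
        "codel_1p19q": 0.05,
        "atrx": 0.05,
        "tertp": 0.08,
        "egfr_amp": 0.05,
        "gain7_loss10": 0.08,
        "cdkn2ab_hd": 0.05,
    }


def _default_medians() -> dict[str, float]:
    # months; published group medians where defined, plausible values where
    # the published curve never reached 0.5 (grade-2 oligodendroglioma) or
    # the group is too small to print (pediatric exits, unknown histology)
    return {
        "oligo2": 140.0,
        "oligo3": 90.5,
        "astro2": 105.1,
        "astro3": 67.4,
        "astro4": 38.7,
        "gbm": 14.0,
        "ped_k27": 12.0,
        "ped_g34": 18.0,
        "excluded": 20.0,
    }


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    legacy_counts: dict[str, int] = field(default_factory=lambda: {
        "oligodendroglioma": 174,
        "oligoastrocytoma": 114,
        "astrocytoma": 169,
        "glioblastoma": 590,
        "unknown": 75,
    })
    truth_mix: dict[str, dict[str, float]] = field(default_factory=_default_truth_mix)
    grade3_fraction: float = 0.45          # P(grade 3 | lower-grade truth)
    atrx_mut_in_astro: float = 0.7
    missingness: dict[str, float] = field(default_factory=_default_missingness)
    os_missing_rate: float = 0.05
    genomic_data_rate: float = 0.85        # P(case has MAF records at all)
    # expression
    n_background_genes: int = 200
    n_class_marker_genes: int = 30         # per CNS5 family block
    n_signature_genes: int = 50            # per glioblastoma subtype
    effect_size_sd: float = 2.0            # class-block shift in within-class SD units
    within_sd: float = 1.0                 # log2-scale within-class SD
    n_multi_aliquot_cases: int = 18
    aliquot_noise_sd: float = 1.0
    # methylation
    n_meth_background_genes: int = 100
    n_meth_marker_genes: int = 30
    meth_effect: float = 0.35              # beta-scale shift of class blocks
    probes_per_gene: int = 2
    probe_noise_sd: float = 0.03
    # survival
    class_median_os: dict[str, float] = field(default_factory=_default_medians)
    censor_rate: float = 0.30
    seed: int = 17

    def __post_init__(self) -> None:
        for name, mix in self.truth_mix.items():
            total = sum(mix.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"truth mix for {name!r} sums to {total}, not 1")
            if any(p < 0 for p in mix.values()):
                raise ValueError("truth-mix probabilities must be non-negative")
        if any(not 0 <= r <= 1 for r in self.missingness.values()):
            raise ValueError("missingness rates must lie in [0, 1]")
        if any(m <= 0 for m in self.class_median_os.values()):
            raise ValueError("median survivals must be positive")
        if any(n < 0 for n in self.legacy_counts.values()):
            raise ValueError("cohort counts must be non-negative")


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed % (2**31), stream])


_AGE_BY_FAMILY = {"oligo": (43, 11), "astro": (40, 12), "gbm": (60, 12), "ped": (25, 5), "excluded": (55, 15)}


def _draw_class(legacy: str, cfg: SimConfig, rng: np.random.Generator) -> str:
    if legacy == "unknown":
        return "excluded"
    mix = cfg.truth_mix[legacy]
    family = rng.choice(list(mix), p=np.array(list(mix.values())) / sum(mix.values()))
    if legacy == "glioblastoma":
        if family == "astro":
            family = "astro4"
        return family
    if family in ("oligo", "astro"):
        grade = 3 if rng.random() < cfg.grade3_fraction else 2
        return f"{family}{grade}"
    return family


def _features_for_class(cls: str, legacy: str, cfg: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    f = {
        "codel_1p19q": "no", "atrx": "wildtype", "tertp": "wildtype",
        "egfr_amp": "no", "gain7_loss10": "no", "cdkn2ab_hd": "no",
        "idh_status": "wildtype", "h3_status": "wildtype",
    }
    if legacy == "glioblastoma":
        f["hist_grade"] = "IV"
    elif legacy == "unknown":
        f["hist_grade"] = "unknown"
    else:
        f["hist_grade"] = "III" if cls.endswith("3") else ("II" if cls.endswith("2") else
                                                           ("III" if rng.random() < 0.5 else "II"))
    if cls.startswith("oligo"):
        f.update(idh_status="mutant", codel_1p19q="yes")
        if rng.random() < 0.8:
            f["tertp"] = "mutant"
    elif cls.startswith("astro"):
        f["idh_status"] = "mutant"
        if rng.random() < cfg.atrx_mut_in_astro:
            f["atrx"] = "mutant"
        if cls == "astro4":
            # legacy lower-grade cases need the CDKN2A/B route to grade 4
            if legacy != "glioblastoma" or rng.random() < 0.5:
                f["cdkn2ab_hd"] = "yes"
    elif cls == "gbm":
        tert = rng.random() < 0.7
        egfr = rng.random() < 0.45
        g7 = rng.random() < 0.6
        if legacy != "glioblastoma" and not (tert or egfr or g7):
            tert = True  # molecular-glioblastoma calls need >= 1 qualifying feature
        f["tertp"] = "mutant" if tert else "wildtype"
        f["egfr_amp"] = "yes" if egfr else "no"
        f["gain7_loss10"] = "yes" if g7 else "no"
        if rng.random() < 0.3:
            f["cdkn2ab_hd"] = "yes"
    elif cls == "ped_k27":
        f["h3_status"] = "K27M"
    elif cls == "ped_g34":
        f["h3_status"] = "G34_mut"
    elif cls == "excluded":
        # unknown histology: plausible GBM-like molecular background
        f["idh_status"] = "mutant" if rng.random() < 0.2 else "wildtype"
        if rng.random() < 0.5:
            f["tertp"] = "mutant"
    return f


def simulate_cohort(cfg: SimConfig) -> tuple[list[CaseAnnotation], pd.DataFrame]:
    """Annotations plus the latent-truth table.

    The truth frame has one row per case: latent class, CNS5 category and
    grade, the true (pre-masking) IDH and H3 statuses, and whether the case
    has genomic (MAF) data.
    """
    rng = _rng(cfg, 0)
    cases: list[CaseAnnotation] = []
    truth_rows = []
    i = 0
    for legacy in ("oligodendroglioma", "oligoastrocytoma", "astrocytoma", "glioblastoma", "unknown"):
        for _ in range(cfg.legacy_counts.get(legacy, 0)):
            i += 1
            case_id = f"SIM-{i:04d}"
            cls = _draw_class(legacy, cfg, rng)
            feats = _features_for_class(cls, legacy, cfg, rng)
            family = "ped" if cls.startswith("ped") else ("excluded" if cls == "excluded" else cls.rstrip("234"))
            mu, sd = _AGE_BY_FAMILY[family]
            age = float(np.clip(rng.normal(mu, sd), 18, 90).round(1))
            true_idh, true_h3 = feats["idh_status"], feats["h3_status"]
            has_genomic = bool(rng.random() < cfg.genomic_data_rate)

            observed = dict(feats)
            for field_name, rate in cfg.missingness.items():
                if rng.random() < rate:
                    observed[field_name] = "unknown"
            cases.append(CaseAnnotation(
                case_id=case_id,
                histology=legacy,
                hist_grade=feats["hist_grade"],
                idh_status=observed["idh_status"],
                codel_1p19q=observed["codel_1p19q"],
                atrx=observed["atrx"],
                tertp=observed["tertp"],
                egfr_amp=observed["egfr_amp"],
                gain7_loss10=observed["gain7_loss10"],
                cdkn2ab_hd=observed["cdkn2ab_hd"],
                h3_status=observed["h3_status"],
                age_at_diagnosis=age,
            ))
            category, grade = _CLASSES[cls]
            truth_rows.append({
                "case_id": case_id, "legacy": legacy, "truth_class": cls,
                "true_category": category, "true_grade": grade,
                "true_idh": true_idh, "true_h3": true_h3,
                "has_genomic_data": has_genomic,
            })
    truth = pd.DataFrame(truth_rows).set_index("case_id", drop=False)

    times, events = simulate_survival(truth["truth_class"], cfg)
    os_rng = _rng(cfg, 5)
    for c, t, e in zip(cases, times, events):
        if os_rng.random() >= cfg.os_missing_rate:
            c.os_time = float(round(t, 2))
            c.os_event = int(e)
    return cases, truth


def simulate_survival(truth_classes: Sequence[str] | pd.Series, cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times (rate ln2 / class median) with independent
    exponential censoring.

    The censoring rate parameter is the expected censored fraction: censoring
    times are exponential with rate lambda * r / (1 - r), which for
    exponential event times censors exactly a fraction r in expectation while
    staying independent of the event process (so Kaplan-Meier estimates stay
    unbiased). ``censor_rate=1`` censors every case.
    """
    rng = _rng(cfg, 1)
    classes = list(pd.Series(truth_classes))
    r = cfg.censor_rate
    if not 0 <= r <= 1:
        raise ValueError("censor_rate must lie in [0, 1]")
    lam = np.array([np.log(2) / cfg.class_median_os[c] for c in classes])
    t_event = rng.exponential(1.0 / lam)
    if r == 0:
        return t_event, np.ones(len(classes), dtype=int)
    if r == 1:
        return t_event * rng.random(len(classes)), np.zeros(len(classes), dtype=int)
    t_censor = rng.exponential((1.0 - r) / (lam * r))
    times = np.minimum(t_event, t_censor)
    events = (t_event <= t_censor).astype(int)
    return times, events


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

_FAMILY_BLOCKS = {"oligo": "OLG", "astro": "AST", "gbm": "GBM"}
BIOMARKER_GENES = ("CRNDE", "FREM2", "SPRY1")
RISK_GENES = ("FN1", "ITGA5", "OSMR", "NGFR")


def _pathway_gene_names(n_act: int, n_rep: int) -> tuple[list[str], list[str]]:
    return ([f"PWA{i:02d}" for i in range(1, n_act + 1)],
            [f"PWR{i:02d}" for i in range(1, n_rep + 1)])


def toy_frem2_pathways() -> list[PathwayDefinition]:
    """Three nested FREM2-like pathway variants (interaction depth 1/2/3).

    Activators (ARR 1 or 0.5) are planted up-regulated and repressors
    (ARR -1 or -0.5) down-regulated in the glioblastoma class by the
    expression simulator, so pathway activation separates GBM from
    IDH-mutant tumors on synthetic cohorts.
    """
    acts, reps = _pathway_gene_names(24, 12)
    depths = [(8, 2), (16, 6), (24, 12)]
    out = []
    for d, (na, nr) in enumerate(depths, start=1):
        members: dict[str, float] = {"FREM2": 1.0}
        for j, g in enumerate(acts[:na]):
            members[g] = 1.0 if j % 2 == 0 else 0.5
        for j, g in enumerate(reps[:nr]):
            members[g] = -1.0 if j % 2 == 0 else -0.5
        out.append(PathwayDefinition(f"FREM2_depth{d}", members, {"depth": d}))
    return out


def simulate_expression(
    truth: pd.DataFrame,
    cfg: SimConfig,
    effect_size_sd: float | None = None,
) -> tuple[ExpressionMatrix, dict]:
    """Gene x aliquot matrix with planted class blocks.

    Log-normal baseline (per-gene log2 mean ~ N(6, 1.5), within-class SD
    ``cfg.within_sd``); per-family marker blocks, subtype-signature blocks
    within the glioblastoma class, biomarker/risk genes and pathway genes
    shifted by ``effect_size_sd`` (in SD units, on the log2 scale). A fixed
    number of cases contribute two aliquots with extra within-case noise.

    Returns the matrix plus a dict of planted objects: ``signatures``,
    ``pathways``, ``subtype_truth`` (per GBM case) and ``class_blocks``.
    """
    effect = cfg.effect_size_sd if effect_size_sd is None else effect_size_sd
    rng = _rng(cfg, 2)
    acts, reps = _pathway_gene_names(24, 12)
    genes: list[str] = [f"BG{i:04d}" for i in range(1, cfg.n_background_genes + 1)]
    blocks = {fam: [f"{tag}{i:03d}" for i in range(1, cfg.n_class_marker_genes + 1)]
              for fam, tag in _FAMILY_BLOCKS.items()}
    for b in blocks.values():
        genes += b
    signatures = [
        SubtypeSignature(name, tuple(f"{name[:2].upper()}SIG{i:03d}" for i in range(1, cfg.n_signature_genes + 1)))
        for name in SUBTYPE_NAMES
    ] if cfg.n_signature_genes > 0 else []
    for s in signatures:
        genes += list(s.genes)
    genes += list(BIOMARKER_GENES) + list(RISK_GENES)  # FREM2 doubles as a pathway member
    genes += acts + reps

    cases = truth["case_id"].tolist()
    families = [("ped" if c.startswith("ped") else ("excluded" if c == "excluded" else c.rstrip("234")))
                for c in truth["truth_class"]]
    subtype_truth = pd.Series(
        {cid: rng.choice(SUBTYPE_NAMES) for cid, fam in zip(cases, families) if fam == "gbm"},
        dtype=object,
    )

    gene_index = pd.Index(genes)
    base_mu = rng.normal(6.0, 1.5, size=len(gene_index))
    shift = pd.DataFrame(0.0, index=gene_index, columns=cases)
    for cid, fam in zip(cases, families):
        if fam in blocks:
            shift.loc[blocks[fam], cid] += effect * cfg.within_sd
        if fam == "gbm":
            if signatures:
                sig = next(s for s in signatures if s.name == subtype_truth[cid])
                shift.loc[list(sig.genes), cid] += effect * cfg.within_sd
            shift.loc[list(BIOMARKER_GENES), cid] += effect * cfg.within_sd
            shift.loc[list(RISK_GENES), cid] += effect * cfg.within_sd
            shift.loc[acts, cid] += effect * cfg.within_sd
            shift.loc[reps, cid] -= effect * cfg.within_sd

    aliquots: list[str] = []
    aliquot_to_case: dict[str, str] = {}
    multi = cases[: min(cfg.n_multi_aliquot_cases, len(cases))]
    cols = {}
    for cid in cases:
        n_ali = 2 if cid in multi else 1
        for a in range(1, n_ali + 1):
            ali = f"{cid}-a{a}" if n_ali > 1 else cid
            noise = rng.normal(0.0, cfg.within_sd, size=len(gene_index))
            extra = rng.normal(0.0, cfg.aliquot_noise_sd, size=len(gene_index)) if a > 1 else 0.0
            log2x = base_mu + shift[cid].to_numpy() + noise + extra
            cols[ali] = np.power(2.0, log2x)
            aliquots.append(ali)
            aliquot_to_case[ali] = cid
    values = pd.DataFrame(cols, index=gene_index)
    expr = ExpressionMatrix(values, aliquot_to_case)
    planted = {
        "signatures": signatures,
        "pathways": toy_frem2_pathways(),
        "subtype_truth": subtype_truth,
        "class_blocks": blocks,
    }
    return expr, planted


def simulate_methylation(truth: pd.DataFrame, cfg: SimConfig) -> MethylationMatrix:
    """Probe-level beta matrix with class-shifted gene blocks.

    Per-family marker genes are hyper-methylated (IDH-mutant families) or
    hypo-methylated (GBM) around a 0.45 baseline; each gene gets
    ``cfg.probes_per_gene`` probes with small probe-level noise.
    """
    rng = _rng(cfg, 3)
    genes = [f"MBG{i:04d}" for i in range(1, cfg.n_meth_background_genes + 1)]
    blocks = {fam: [f"M{tag}{i:03d}" for i in range(1, cfg.n_meth_marker_genes + 1)]
              for fam, tag in _FAMILY_BLOCKS.items()}
    for b in blocks.values():
        genes += b

    cases = truth["case_id"].tolist()
    families = [("ped" if c.startswith("ped") else ("excluded" if c == "excluded" else c.rstrip("234")))
                for c in truth["truth_class"]]
    gene_means = pd.DataFrame(0.45, index=pd.Index(genes), columns=cases)
    for cid, fam in zip(cases, families):
        if fam in ("oligo", "astro"):
            gene_means.loc[blocks[fam], cid] += cfg.meth_effect
        elif fam == "gbm":
            gene_means.loc[blocks["gbm"], cid] -= cfg.meth_effect

    probe_rows = {}
    probe_to_gene = {}
    for gene in genes:
        for pnum in range(1, cfg.probes_per_gene + 1):
            probe = f"cg_{gene}_{pnum}"
            probe_to_gene[probe] = gene
            vals = gene_means.loc[gene].to_numpy() + rng.normal(0, cfg.probe_noise_sd, size=len(cases))
            probe_rows[probe] = np.clip(vals, 0.0, 1.0)
    values = pd.DataFrame.from_dict(probe_rows, orient="index", columns=cases)
    return MethylationMatrix(values, probe_to_gene, gene_level=False)


def simulate_maf(truth: pd.DataFrame, cfg: SimConfig) -> list[MafRecord]:
    """MAF records consistent with each case's true IDH/H3 status.

    Cases without genomic data are absent from the MAF universe entirely
    (their statuses stay unknown upstream); every case with genomic data
    gets at least one record so wildtype is distinguishable from missing.
    """
    rng = _rng(cfg, 4)
    records: list[MafRecord] = []
    for row in truth.itertuples():
        if not row.has_genomic_data:
            continue
        sid = row.case_id
        if row.true_idh == "mutant":
            if rng.random() < 0.9:
                records.append(MafRecord(sid, "IDH1", "Missense_Mutation", "p.R132H"))
            else:
                records.append(MafRecord(sid, "IDH2", "Missense_Mutation", "p.R172K"))
        if row.true_h3 == "K27M":
            gene = "H3F3A" if rng.random() < 0.8 else "HIST1H3B"
            records.append(MafRecord(sid, gene, "Missense_Mutation", "p.K28M"))
        elif row.true_h3 == "G34_mut":
            records.append(MafRecord(sid, "H3F3A", "Missense_Mutation", "p.G35R"))
        # passenger row guarantees presence in the MAF universe
        records.append(MafRecord(sid, "TP53", "Missense_Mutation", "p.R273H"))
        if rng.random() < 0.3:
            records.append(MafRecord(sid, "TTN", "Silent", "p.A100A"))
    return records
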