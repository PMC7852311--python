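"""Synthetic pan-tumor cohort generator with planted, recoverable structure.

The generator emulates every input of a pan-cancer matrisome regulation
study: a log2(x+1)-scale expression matrix with matched healthy tissues,
a categorized matrisome gene list, TF->target prior interactions from four
textual sources plus CAGE-style TF-presence and TF-binding-site enrichment
evidence, driver mutation-frequency tables, a protein-protein interaction
edge list, immunohistochemistry staining levels, survival follow-up with
censoring, and a drug-gene interaction table with FDA-label annotations.

Everything worth recovering downstream is planted explicitly and recorded
in a :class:`GroundTruth` sidecar: per-tumor signature genes (up-shifted on
the log2 scale), TF->target modules with controlled in-tumor vs out-of-tumor
Pearson correlation, master-regulator drivers that pass the mutation
frequency and PPI-coverage filters by construction, and prognostic modules
whose high/low activity strata differ in hazard.

Correlated pairs use a shared-latent construction on the z scale:
``z_target = alpha * z_tf + sqrt(1 - alpha^2) * noise`` with ``alpha``
equal to the requested Pearson r, which controls the population
correlation in closed form.  Each generator stage draws from an
independent substream of the root seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig

MATRISOME_CATEGORIES = (
    "basement membranes",
    "collagens",
    "ECM-affiliated",
    "ECM glycoproteins",
    "ECM regulators",
    "proteoglycans",
    "secreted factors",
)

TEXTUAL_SOURCES = ("sourceA", "sourceB", "sourceC", "sourceD")
FUNCTIONAL_SOURCES = ("fantom_presence", "tfbs_enrichment")
ALL_SOURCES = TEXTUAL_SOURCES + FUNCTIONAL_SOURCES

STAINING_LEVELS = ("High", "Medium", "Low", "Not detected")

_SYSTEMS = ("digestive", "respiratory", "nervous", "urogenital", "endocrine")

# stage tags for independent substreams off the root seed
_STAGES = {"cohort": 1, "priors": 2, "driver_ppi": 3, "survival": 4, "staining_drugs": 5}


def _rng(config: SimConfig, stage: str, extra: int | None = None) -> np.random.Generator:
    entropy = [_STAGES[stage], config.seed]
    if extra is not None:
        entropy.append(extra)
    return np.random.default_rng(entropy)


@dataclass
class GroundTruth:
    """Planted structure of one synthetic cohort — the recovery oracle.

    ``planted_prognostic`` maps tumor -> list of ((tf, target), direction)
    where direction is ``"noxious"`` (high activity -> worse survival) or
    ``"favorable"`` (high activity -> better survival).
    """

    planted_signatures: dict[str, set[str]]
    planted_modules: dict[str, set[tuple[str, str]]]
    planted_masters: dict[str, set[str]]
    planted_prognostic: dict[str, list[tuple[tuple[str, str], str]]]
    tumor_types: list[str] = field(default_factory=list)
    tf_ids: list[str] = field(default_factory=list)
    matrisome_ids: list[str] = field(default_factory=list)
    master_classes: dict[str, str] = field(default_factory=dict)

    def module_tfs(self, tumor: str) -> set[str]:
        return {tf for tf, _ in self.planted_modules.get(tumor, set())}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_signatures": {t: sorted(g) for t, g in self.planted_signatures.items()},
            "planted_modules": {
                t: sorted(list(p) for p in pairs) for t, pairs in self.planted_modules.items()
            },
            "planted_masters": {t: sorted(m) for t, m in self.planted_masters.items()},
            "planted_prognostic": {
                t: [[list(pair), d] for pair, d in mods]
                for t, mods in self.planted_prognostic.items()
            },
            "tumor_types": self.tumor_types,
            "tf_ids": self.tf_ids,
            "matrisome_ids": self.matrisome_ids,
            "master_classes": self.master_classes,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_signatures={t: set(g) for t, g in payload["planted_signatures"].items()},
            planted_modules={
                t: {tuple(p) for p in pairs} for t, pairs in payload["planted_modules"].items()
            },
            planted_masters={t: set(m) for t, m in payload["planted_masters"].items()},
            planted_prognostic={
                t: [(tuple(pair), d) for pair, d in mods]
                for t, mods in payload["planted_prognostic"].items()
            },
            tumor_types=payload["tumor_types"],
            tf_ids=payload["tf_ids"],
            matrisome_ids=payload["matrisome_ids"],
            master_classes=payload["master_classes"],
        )


def _gene_ids(config: SimConfig) -> tuple[list[str], list[str], list[str]]:
    mat = [f"MG{i:04d}" for i in range(config.n_matrisome)]
    tfs = [f"TF{i:03d}" for i in range(config.n_tfs)]
    n_fill = config.n_genes - config.n_matrisome - config.n_tfs
    fill = [f"G{i:04d}" for i in range(n_fill)]
    return mat, tfs, fill


def generate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate expression, sample annotation, matrisome catalog and truth.

    Returns
    -------
    expr:
        genes x samples DataFrame on the log2(x+1) scale (values >= 0).
    annot:
        one row per sample: sample_id, tumor_type, system_of_origin,
        sample_class, survival_days (NaN until :func:`generate_survival`),
        event.
    catalog:
        two columns (gene_id, category) over the matrisome genes.
    truth:
        planted signatures, modules, masters and prognostic effects.

    Tumor baseline means are drawn once per (gene, tumor) from a shared
    hyper-distribution, so tumors are separable without hand-tuning;
    matched healthy samples share the tumor's baseline and differ only by
    the planted signature shift, making the shift the sole tumor-vs-healthy
    signal.
    """
    config.validate()
    rng = _rng(config, "cohort")

    mat, tfs, fill = _gene_ids(config)
    gene_ids = mat + tfs + fill
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    tumors = [f"TUM{i:02d}" for i in range(1, config.n_tumor_types + 1)]

    # planted signatures: disjoint blocks of matrisome genes
    spt = config.signature_genes_per_tumor
    signatures = {t: set(mat[i * spt : (i + 1) * spt]) for i, t in enumerate(tumors)}

    # planted modules: targets are the first planted_modules_per_tumor
    # signature genes; TFs sampled without replacement within each tumor
    modules: dict[str, set[tuple[str, str]]] = {}
    for i, t in enumerate(tumors):
        targets = sorted(signatures[t])[: config.planted_modules_per_tumor]
        chosen_tfs = rng.choice(tfs, size=len(targets), replace=False)
        modules[t] = set(zip((str(x) for x in chosen_tfs), targets))

    # planted masters: tumor-specific drivers from the filler pool, plus one
    # pan-cancer driver mastering the first two tumors (a "common" regulator)
    masters: dict[str, set[str]] = {t: set() for t in tumors}
    master_classes: dict[str, str] = {}
    cursor = 0
    for t in tumors:
        for _ in range(config.masters_per_tumor):
            gene = fill[cursor]
            cursor += 1
            masters[t].add(gene)
            master_classes[gene] = "tumor-specific"
    pan_gene = fill[cursor]
    master_classes[pan_gene] = "pan-cancer"
    for t in tumors[: min(2, len(tumors))]:
        masters[t].add(pan_gene)

    # planted prognostic modules with alternating direction
    prognostic: dict[str, list[tuple[tuple[str, str], str]]] = {}
    for t in tumors:
        ordered = sorted(modules[t])
        picks = ordered[: config.prognostic_modules_per_tumor]
        prognostic[t] = [
            (pair, "noxious" if j % 2 == 0 else "favorable") for j, pair in enumerate(picks)
        ]

    truth = GroundTruth(
        planted_signatures=signatures,
        planted_modules=modules,
        planted_masters=masters,
        planted_prognostic=prognostic,
        tumor_types=tumors,
        tf_ids=tfs,
        matrisome_ids=mat,
        master_classes=master_classes,
    )

    # sample bookkeeping: tumor blocks then healthy blocks, fixed order
    sample_ids: list[str] = []
    annot_rows: list[dict] = []
    blocks: list[tuple[str, str, slice]] = []  # (tumor, class, column slice)
    col = 0
    for i, t in enumerate(tumors):
        ids = [f"{t}_T{j:03d}" for j in range(config.samples_per_tumor)]
        sample_ids.extend(ids)
        blocks.append((t, "primary", slice(col, col + len(ids))))
        col += len(ids)
        for s in ids:
            annot_rows.append(
                {
                    "sample_id": s,
                    "tumor_type": t,
                    "system_of_origin": _SYSTEMS[i % len(_SYSTEMS)],
                    "sample_class": "primary",
                }
            )
    for i, t in enumerate(tumors):
        ids = [f"{t}_H{j:03d}" for j in range(config.healthy_per_tissue)]
        sample_ids.extend(ids)
        blocks.append((t, "healthy", slice(col, col + len(ids))))
        col += len(ids)
        for s in ids:
            annot_rows.append(
                {
                    "sample_id": s,
                    "tumor_type": t,
                    "system_of_origin": _SYSTEMS[i % len(_SYSTEMS)],
                    "sample_class": "healthy",
                }
            )
    n_samples = col

    # baseline means: gene-level mean + per-(gene, tumor) offset
    gene_mu = rng.normal(config.baseline_mean, config.baseline_gene_sd, config.n_genes)
    offsets = rng.normal(0.0, config.tumor_offset_sd, (config.n_genes, config.n_tumor_types))
    tumor_index = {t: i for i, t in enumerate(tumors)}

    z = rng.standard_normal((config.n_genes, n_samples))

    # impose planted correlations block by block (the original z row of the
    # target serves as its independent noise term)
    owner_of: dict[str, tuple[str, str]] = {}
    for t, pairs in modules.items():
        for tf, target in pairs:
            owner_of[target] = (t, tf)
    for target, (owner, tf) in owner_of.items():
        ti, gi = gene_index[target], gene_index[tf]
        for t, cls, sl in blocks:
            alpha = config.r_in if (t == owner and cls == "primary") else config.r_out
            z[ti, sl] = alpha * z[gi, sl] + np.sqrt(1.0 - alpha**2) * z[ti, sl]

    means = np.empty((config.n_genes, n_samples))
    for t, cls, sl in blocks:
        means[:, sl] = (gene_mu + offsets[:, tumor_index[t]])[:, None]
        if cls == "primary":
            sig_rows = [gene_index[g] for g in sorted(signatures[t])]
            means[sig_rows, sl] += config.signature_log2_shift
        # master drivers are elevated tissue-wide (tumor AND matched
        # healthy), so the tumor-vs-healthy comparison stays null for them
        master_rows = [gene_index[g] for g in sorted(masters[t])]
        means[master_rows, sl] += config.master_log2_shift

    values = np.clip(means + config.noise_sd * z, 0.0, None)
    expr = pd.DataFrame(values, index=gene_ids, columns=sample_ids)

    annot = pd.DataFrame(annot_rows)
    annot["survival_days"] = np.nan
    annot["event"] = 0

    catalog = pd.DataFrame(
        {
            "gene_id": mat,
            "category": [MATRISOME_CATEGORIES[i % len(MATRISOME_CATEGORIES)] for i in range(len(mat))],
        }
    )
    return expr, annot, catalog, truth


def _check_truth(config: SimConfig, truth: GroundTruth) -> None:
    if len(truth.tumor_types) != config.n_tumor_types:
        raise ValueError("truth/config mismatch: tumor-type count differs")
    per_tumor = {len(m) for m in truth.planted_modules.values()}
    if per_tumor and per_tumor != {config.planted_modules_per_tumor}:
        raise ValueError("truth/config mismatch: planted module counts differ")


def generate_priors(config: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Emit the TF->target prior-interaction table (tf, target, source rows).

    Each of the six sources independently reports a true pair with
    probability ``prior_coverage``; afterwards a structural guarantee is
    enforced so every planted module is recoverable by the downstream
    consensus rule: at least one functional source (fantom_presence or
    tfbs_enrichment) and at least two sources in total.  Decoy (unplanted)
    pairs are added at exactly ``decoy_rate`` per true pair with random
    source membership, targeting signature genes so they survive mining
    and stress the correlation filters.
    """
    _check_truth(config, truth)
    rng = _rng(config, "priors")

    planted = sorted(
        (tf, target) for pairs in truth.planted_modules.values() for tf, target in pairs
    )
    rows: list[dict] = []
    for tf, target in planted:
        present = [s for s in ALL_SOURCES if rng.random() < config.prior_coverage]
        if not any(s in FUNCTIONAL_SOURCES for s in present):
            present.append("fantom_presence")
        if len(present) < 2:
            extra = str(rng.choice(TEXTUAL_SOURCES))
            if extra not in present:
                present.append(extra)
        for s in sorted(present, key=ALL_SOURCES.index):
            rows.append({"tf": tf, "target": target, "source": s})

    planted_set = set(planted)
    sig_genes = sorted(g for genes in truth.planted_signatures.values() for g in genes)
    n_decoys = config.decoy_rate * len(planted)
    decoys: set[tuple[str, str]] = set()
    while len(decoys) < n_decoys:
        tf = str(rng.choice(truth.tf_ids))
        target = str(rng.choice(sig_genes))
        if tf != target and (tf, target) not in planted_set and (tf, target) not in decoys:
            decoys.add((tf, target))
    for tf, target in sorted(decoys):
        k = int(rng.integers(1, 4))
        chosen = rng.choice(len(ALL_SOURCES), size=k, replace=False)
        for i in sorted(chosen):
            rows.append({"tf": tf, "target": target, "source": ALL_SOURCES[i]})

    priors = pd.DataFrame(rows, columns=["tf", "target", "source"])
    return priors.drop_duplicates().reset_index(drop=True)


def generate_driver_ppi(
    config: SimConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Driver mutation-frequency table and PPI edge list.

    Planted masters pass both downstream filters with a margin, by
    construction: tumor-specific masters carry ``driver_freq_specific``
    (> 5%) in their tumor; the pan-cancer master's frequency in its owning
    tumors exceeds its own cross-cohort mean; every master receives PPI
    edges to ``master_tf_fraction`` of the owning tumor's planted module
    TFs (well above the 10% coverage cut).  Decoy drivers fail at least
    one filter: either sub-threshold frequency, or no PPI edge to any
    module TF.
    """
    _check_truth(config, truth)
    rng = _rng(config, "driver_ppi")
    tumors = truth.tumor_types

    driver_rows: list[dict] = []
    ppi_pairs: set[tuple[str, str]] = set()
    evid_rows: list[dict] = []

    def add_edge(a: str, b: str, evidence: str) -> None:
        if a == b:
            return
        key = (a, b) if a < b else (b, a)
        if key in ppi_pairs:
            return
        ppi_pairs.add(key)
        evid_rows.append({"protein_a": key[0], "protein_b": key[1], "evidence": evidence})

    pan_genes = sorted(g for g, c in truth.master_classes.items() if c == "pan-cancer")
    for t in tumors:
        tumor_tfs = sorted(truth.module_tfs(t))
        n_link = max(int(np.ceil(config.master_tf_fraction * len(tumor_tfs))), 2)
        for gene in sorted(truth.planted_masters[t]):
            if truth.master_classes[gene] == "tumor-specific":
                driver_rows.append(
                    {
                        "gene": gene,
                        "tumor_type": t,
                        "mutation_frequency": config.driver_freq_specific,
                        "driver_class": "tumor-specific",
                    }
                )
            linked = rng.choice(tumor_tfs, size=min(n_link, len(tumor_tfs)), replace=False)
            for tf in linked:
                add_edge(gene, str(tf), "affinity-capture western")

    # pan-cancer master: high frequency in owning tumors, low elsewhere,
    # so in-tumor frequency > cross-cohort mean exactly where planted
    for gene in pan_genes:
        owners = {t for t in tumors if gene in truth.planted_masters[t]}
        for t in tumors:
            driver_rows.append(
                {
                    "gene": gene,
                    "tumor_type": t,
                    "mutation_frequency": 0.15 if t in owners else 0.03,
                    "driver_class": "pan-cancer",
                }
            )

    # decoy drivers: half fail the frequency filter, half fail PPI coverage
    mat, tfs, fill = _gene_ids(config)
    used = set(truth.master_classes)
    decoy_pool = [g for g in fill if g not in used]
    ci = 0
    for t in tumors:
        for j in range(config.decoy_drivers_per_tumor):
            gene = decoy_pool[ci]
            ci += 1
            if j % 2 == 0:
                # passes frequency, gets zero edges to module TFs
                driver_rows.append(
                    {
                        "gene": gene,
                        "tumor_type": t,
                        "mutation_frequency": config.driver_freq_specific,
                        "driver_class": "tumor-specific",
                    }
                )
            else:
                # fails frequency (0.04 <= 5%), may have edges
                driver_rows.append(
                    {
                        "gene": gene,
                        "tumor_type": t,
                        "mutation_frequency": 0.04,
                        "driver_class": "tumor-specific",
                    }
                )
                for tf in sorted(truth.module_tfs(t))[:3]:
                    add_edge(gene, tf, "two-hybrid")

    # background noise edges among filler proteins
    for _ in range(config.ppi_noise_edges):
        a, b = rng.choice(decoy_pool[ci:], size=2, replace=False)
        add_edge(str(a), str(b), "two-hybrid")

    drivers = pd.DataFrame(
        driver_rows, columns=["gene", "tumor_type", "mutation_frequency", "driver_class"]
    )
    ppi = pd.DataFrame(evid_rows, columns=["protein_a", "protein_b", "evidence"])
    return drivers, ppi


def generate_survival(
    config: SimConfig,
    truth: GroundTruth,
    expr: pd.DataFrame,
    annot: pd.DataFrame,
) -> pd.DataFrame:
    """Fill survival_days/event for tumor samples (healthy stay NaN).

    Times are exponential.  A sample's hazard is the baseline multiplied by
    ``hazard_ratio_prognostic`` once per planted prognostic module for
    which the sample sits in the at-risk stratum: the high-activity
    stratum for a noxious module, the low-activity stratum for a favorable
    one (activity = mean of the TF and target log2 expression, dichotomized
    at the within-tumor mean).  Censoring is independent, calibrated so the
    per-sample censoring probability equals ``censoring_rate`` exactly.
    """
    _check_truth(config, truth)
    rng = _rng(config, "survival")
    lam0 = np.log(2.0) / config.baseline_median_survival_days
    out = annot.copy()
    out["survival_days"] = np.nan
    out["event"] = 0

    for t in truth.tumor_types:
        mask = (out["tumor_type"] == t) & (out["sample_class"] != "healthy")
        samples = out.loc[mask, "sample_id"].tolist()
        lam = np.full(len(samples), lam0)
        for (tf, target), direction in truth.planted_prognostic.get(t, []):
            activity = expr.loc[[tf, target], samples].mean(axis=0).to_numpy()
            high = activity > activity.mean()
            at_risk = high if direction == "noxious" else ~high
            lam = lam * np.where(at_risk, config.hazard_ratio_prognostic, 1.0)
        times = rng.exponential(1.0 / lam)
        if config.censoring_rate > 0:
            lam_c = lam * config.censoring_rate / (1.0 - config.censoring_rate)
            censor = rng.exponential(1.0 / lam_c)
        else:
            censor = np.full(len(samples), np.inf)
        observed = np.minimum(times, censor)
        event = (times <= censor).astype(int)
        out.loc[mask, "survival_days"] = observed
        out.loc[mask, "event"] = event
    return out


def generate_staining_drugs(
    config: SimConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Immunohistochemistry staining records and a drug-gene table.

    Staining levels are multinomial per (protein, sample) over
    High/Medium/Low/Not detected with ``staining_probs``.  The drug table
    covers ``drug_coverage`` of each architecture layer (signature
    matrisome genes, module TFs, masters); a ``mechanism_missing_rate``
    fraction of extra rows is emitted with an empty mechanism, which the
    loader must drop.
    """
    _check_truth(config, truth)
    rng = _rng(config, "staining_drugs")

    proteins = sorted(
        {g for s in truth.planted_signatures.values() for g in s}
        | {tf for t in truth.tumor_types for tf in truth.module_tfs(t)}
        | {m for s in truth.planted_masters.values() for m in s}
    )
    stain_rows = []
    for p in proteins:
        levels = rng.choice(len(STAINING_LEVELS), size=config.staining_samples,
                            p=list(config.staining_probs))
        for j, li in enumerate(levels):
            stain_rows.append(
                {"protein": p, "sample_id": f"IHC{j:03d}", "level": STAINING_LEVELS[li]}
            )
    staining = pd.DataFrame(stain_rows, columns=["protein", "sample_id", "level"])

    mechanisms = ("inhibitor", "antagonist", "antibody", "agonist")
    tumors = truth.tumor_types
    drug_rows = []
    for gene in proteins:
        if rng.random() >= config.drug_coverage:
            continue
        mech = str(rng.choice(mechanisms))
        approved = bool(rng.random() < 0.6)
        n_lab = int(rng.integers(0, 3)) if approved else 0
        labels = sorted(str(x) for x in rng.choice(tumors, size=n_lab, replace=False))
        drug_rows.append(
            {
                "drug": f"DRUG_{gene}",
                "gene": gene,
                "mechanism": mech,
                "fda_approved_cancer_drug": approved,
                "approved_tumor_types": ";".join(labels),
            }
        )
        if rng.random() < config.mechanism_missing_rate:
            drug_rows.append(
                {
                    "drug": f"DRUGX_{gene}",
                    "gene": gene,
                    "mechanism": "",
                    "fda_approved_cancer_drug": False,
                    "approved_tumor_types": "",
                }
            )
    drugs = pd.DataFrame(
        drug_rows,
        columns=["drug", "gene", "mechanism", "fda_approved_cancer_drug", "approved_tumor_types"],
    )
    return staining, drugs


def generate_all(config: SimConfig):
    """Run every generator stage; returns a dict of all study inputs."""
    expr, annot, catalog, truth = generate_cohort(config)
    priors = generate_priors(config, truth)
    drivers, ppi = generate_driver_ppi(config, truth)
    annot = generate_survival(config, truth, expr, annot)
    staining, drugs = generate_staining_drugs(config, truth)
    return {
        "expr": expr,
        "annot": annot,
        "catalog": catalog,
        "truth": truth,
        "priors": priors,
        "drivers": drivers,
        "ppi": ppi,
        "staining": staining,
        "drugs": drugs,
    }
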