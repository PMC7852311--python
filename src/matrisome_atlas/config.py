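"""Simulation configuration for synthetic pan-tumor cohorts.

A :class:`SimConfig` fixes every knob of the synthetic-data generator:
cohort geometry (tumor types, samples, genes), the planted regulatory
structure (TF->target correlations inside and outside the owning tumor,
signature shifts), prior-source coverage and decoy contamination, driver
mutation frequencies, and the prognostic hazard model.  All generator
stages derive independent random substreams from the single ``seed``, so
regenerating one table never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic pan-tumor study.

    Parameters
    ----------
    n_tumor_types:
        Number of tumor cohorts; each gets a matched healthy tissue.
    samples_per_tumor:
        Primary-tumor samples per cohort.
    healthy_per_tissue:
        Matched healthy samples per tissue (1:1 with tumor types).
    n_genes:
        Total genes in the expression matrix (matrisome + TF + filler).
    n_matrisome:
        Matrisome genes (each in exactly one of seven categories).
    n_tfs:
        Transcription-factor genes.
    planted_modules_per_tumor:
        True TF->matrisome-target pairs planted per tumor.
    r_in:
        Pearson correlation of a planted pair inside its owning tumor.
    r_out:
        Correlation of the same pair in every other sample group
        (must be strictly below ``r_in``).
    signature_genes_per_tumor:
        Matrisome genes up-shifted in one tumor only (module targets are
        drawn from these).
    signature_log2_shift:
        Mean shift (log2 units) of signature genes in their owning tumor.
    prior_coverage:
        Probability each prior source independently reports a true pair.
    decoy_rate:
        False prior pairs emitted per true pair (integer multiplier).
    driver_freq_specific:
        Mutation frequency given to planted tumor-specific master drivers.
    hazard_ratio_prognostic:
        Hazard ratio applied to the at-risk stratum of planted prognostic
        modules (1 = no survival effect).
    censoring_rate:
        Per-sample probability of independent right-censoring.
    seed:
        Root seed; every stage spawns its own substream from it.
    """

    n_tumor_types: int = 5
    samples_per_tumor: int = 200
    healthy_per_tissue: int = 50
    n_genes: int = 300
    n_matrisome: int = 60
    n_tfs: int = 40
    planted_modules_per_tumor: int = 10
    r_in: float = 0.8
    r_out: float = 0.1
    signature_genes_per_tumor: int = 10
    signature_log2_shift: float = 4.0
    prior_coverage: float = 0.8
    decoy_rate: int = 3
    driver_freq_specific: float = 0.2
    hazard_ratio_prognostic: float = 3.0
    censoring_rate: float = 0.3
    seed: int = 0

    # generator plumbing beyond the core contract
    masters_per_tumor: int = 2
    decoy_drivers_per_tumor: int = 2
    prognostic_modules_per_tumor: int = 2
    baseline_mean: float = 8.0
    baseline_gene_sd: float = 1.5
    tumor_offset_sd: float = 1.0
    noise_sd: float = 1.0
    master_tf_fraction: float = 0.3
    master_log2_shift: float = 1.5
    ppi_noise_edges: int = 100
    staining_samples: int = 12
    staining_probs: tuple[float, float, float, float] = (0.35, 0.25, 0.2, 0.2)
    drug_coverage: float = 0.6
    mechanism_missing_rate: float = 0.1
    baseline_median_survival_days: float = 1000.0

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first violated invariant."""
        counts = {
            "n_tumor_types": self.n_tumor_types,
            "samples_per_tumor": self.samples_per_tumor,
            "healthy_per_tissue": self.healthy_per_tissue,
            "n_genes": self.n_genes,
            "n_matrisome": self.n_matrisome,
            "n_tfs": self.n_tfs,
            "planted_modules_per_tumor": self.planted_modules_per_tumor,
            "signature_genes_per_tumor": self.signature_genes_per_tumor,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1 (got {value})")
        probs = {
            "prior_coverage": self.prior_coverage,
            "driver_freq_specific": self.driver_freq_specific,
            "censoring_rate": self.censoring_rate,
            "drug_coverage": self.drug_coverage,
            "mechanism_missing_rate": self.mechanism_missing_rate,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1] (got {value})")
        if not 0.0 <= self.r_in < 1.0:
            raise ValueError(f"r_in must be in [0, 1) (got {self.r_in})")
        if not 0.0 <= self.r_out < 1.0:
            raise ValueError(f"r_out must be in [0, 1) (got {self.r_out})")
        if self.r_out >= self.r_in:
            raise ValueError(
                f"r_out must be < r_in (got r_out={self.r_out}, r_in={self.r_in})"
            )
        if self.n_matrisome > self.n_genes:
            raise ValueError("n_matrisome must be <= n_genes")
        if self.n_tfs > self.n_genes - self.n_matrisome:
            raise ValueError("n_tfs must be <= n_genes - n_matrisome")
        if self.decoy_rate < 0:
            raise ValueError("decoy_rate must be >= 0")
        if self.hazard_ratio_prognostic <= 0:
            raise ValueError("hazard_ratio_prognostic must be > 0")
        if self.planted_modules_per_tumor > self.signature_genes_per_tumor:
            raise ValueError(
                "planted_modules_per_tumor must be <= signature_genes_per_tumor"
            )
        if self.planted_modules_per_tumor > self.n_tfs:
            raise ValueError("planted_modules_per_tumor must be <= n_tfs")
        if self.n_tumor_types * self.signature_genes_per_tumor > self.n_matrisome:
            raise ValueError(
                "n_tumor_types * signature_genes_per_tumor must be <= n_matrisome "
                "(signatures are planted disjointly)"
            )
        if abs(sum(self.staining_probs) - 1.0) > 1e-9:
            raise ValueError("staining_probs must sum to 1")
        if self.prognostic_modules_per_tumor > self.planted_modules_per_tumor:
            raise ValueError(
                "prognostic_modules_per_tumor must be <= planted_modules_per_tumor"
            )
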