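"""Published reference numbers from a genome-wide monocyte miSNP /
3'UTR-SNP expression scan, used as validation inputs.

The raw cohort data behind the published scan are not distributable, but
its printed summary numbers are: the study dimensions (test counts that fix
the Bonferroni thresholds), the per-gene 3utrSNP histogram, and the 51
genome-wide significant interaction hits with their interaction p-values,
Levene p-values and weighted p-values.  The hits table lets the
Levene-weighted Bonferroni functional form be validated: the reported
weighted p-values are reproduced by dividing each interaction p-value by a
weight proportional to -log10 of its Levene p-value, with a single
normalization constant shared by every row.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .datamodel import GenomicInterval, SnpRecord

__all__ = [
    "STUDY_DIMENSIONS",
    "UTRSNPS_PER_GENE_HISTOGRAM",
    "load_interaction_hits",
    "MI_SNP_MIR1279",
    "PROBE_INTERVALS_MIR1279",
]

#: Study dimensions of the published discovery cohort.  The Bonferroni
#: thresholds are always recomputed from these counts, never hard-coded.
STUDY_DIMENSIONS = {
    "n_misnp": 294,
    "n_mirna_distinct": 258,
    "n_probes_marginal": 22_004,
    "n_genes_marginal": 15_786,
    "n_probes_interaction": 8_768,
    "n_genes_interaction": 6_147,
    "n_3utrsnp": 10_783,
    "n_interaction_tests": 4_890_102,
    "n_replicable_hits": 8,
}

#: Published distribution of the number of 3utrSNPs (or proxies) per gene.
UTRSNPS_PER_GENE_HISTOGRAM = {
    1: 3_435, 2: 1_438, 3: 670, 4: 313, 5: 138, 6: 80, 7: 35,
    8: 17, 9: 7, 10: 4, 11: 5, 12: 1, 13: 1, 14: 2, 18: 1,
}


def load_interaction_hits() -> pd.DataFrame:
    """The 51 published genome-wide significant interaction hits.

    Columns: gene, probe, utr_snp, mirna, mi_snp, p (interaction p-value),
    levene_q (Levene p-value of the 3utrSNP unit), weighted_p.
    """
    with resources.files("mirqtl.data").joinpath(
        "published_interaction_hits.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


#: The pri-miRNA SNP of the published cis/trans example (hsa-mir-1279
#: rs1463335, chromosome 12, printed position 69,667,075).
MI_SNP_MIR1279 = SnpRecord(snp_id="rs1463335", chrom="12", pos=69_667_075 - 1)

#: Probe spans (1-based inclusive as printed) for three genes associated
#: with that miSNP: LYZ and YEATS4 lie within 1 Mb on the same chromosome
#: (cis); CTRC is on another chromosome (trans).
PROBE_INTERVALS_MIR1279 = {
    "LYZ": GenomicInterval.from_1based("12", 69_742_133, 69_748_012),
    "YEATS4": GenomicInterval.from_1based("12", 69_753_531, 69_784_575),
    "CTRC": GenomicInterval.from_1based("1", 15_764_937, 15_773_152),
}


def validate_weighting_scheme(hits: pd.DataFrame | None = None) -> dict:
    """Validate the weighted-Bonferroni functional form on the published hits.

    For each row, the implied weight is P / P*; under w proportional to
    -log10(q) the ratio (P / P*) / (-log10 q) must be one shared constant.
    Rows whose ratio deviates more than two-fold from the median are flagged
    as printed inconsistencies (exponent misprints) and excluded from the
    calibration statistics.

    Returns a dict with the calibration constant from the first consistent
    row, the cross-row CV of the ratio, the maximum relative error of the
    predicted weighted p-values, and the flagged rows.
    """
    import numpy as np

    if hits is None:
        hits = load_interaction_hits()
    ratio = (hits["p"] / hits["weighted_p"]) / (-np.log10(hits["levene_q"]))
    med = ratio.median()
    consistent = (ratio / med < 2.0) & (ratio / med > 0.5)
    flagged = hits.loc[~consistent, ["gene", "mirna", "mi_snp", "utr_snp"]]
    r = ratio[consistent]
    c = float(r.iloc[0])
    predicted = hits.loc[consistent, "p"] / (c * -np.log10(hits.loc[consistent, "levene_q"]))
    rel_err = (predicted - hits.loc[consistent, "weighted_p"]).abs() / hits.loc[consistent, "weighted_p"]
    return {
        "constant": c,
        "cv": float(r.std(ddof=1) / r.mean()),
        "max_rel_err": float(rel_err.max()),
        "n_consistent": int(consistent.sum()),
        "flagged": flagged,
        "predicted": predicted,
    }
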