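"""Curated subtype-specific miRNA fold-change reference values.

Linear fold changes (target subtype versus all other tumors, ratio of
geometric means) for the miRNAs most differentially expressed in each
histological subtype, molecular subtype, and in CTNNB1-mutated tumors of a
119-sample endometrial carcinoma cohort profiled on a 352-miRNA RT-qPCR
panel.  They serve two roles: worked-example inputs for the fold-change
filter, and the simulator's default planted-effect catalogue, so that
default synthetic runs produce screen tables on a realistic effect-size
scale (roughly 0.3x to 15x).
"""

from __future__ import annotations

__all__ = [
    "HISTOLOGY_FOLD_CHANGES",
    "MOLECULAR_FOLD_CHANGES",
    "CTNNB1_FOLD_CHANGES",
    "catalog_fold_changes",
]

# Histological subtypes: miRNA -> linear fold change (one-vs-rest).
HISTOLOGY_FOLD_CHANGES: dict[str, dict[str, float]] = {
    "endometrioid": {
        "miR-449a": 14.9,
        "miR-449b-5p": 13.5,
        "miR-449c-5p": 7.87,
        "miR-375": 4.76,
        "miR-34c-5p": 3.42,
        "miR-187-3p": 3.20,
        "miR-190b": 2.31,
        "miR-184": 2.13,
        "miR-34c-3p": 2.11,
        "miR-17-3p": 1.88,
        "miR-342-5p": 1.81,
        "miR-363-3p": 1.80,
        "miR-568": 1.73,
        "miR-195-5p": 1.72,
        "miR-147a": 1.72,
        "miR-146a-5p": 1.70,
        "miR-34b-3p": 1.70,
        "miR-163": 1.66,
        "miR-145-5p": 1.62,
        "miR-526b-5p": 1.52,
        "miR-504-5p": 1.51,
        "miR-519a-3p": 0.33,
        "miR-301b-3p": 0.33,
        "miR-31-5p": 0.34,
        "miR-590-5p": 0.36,
        "miR-18a-5p": 0.38,
        "miR-18b-5p": 0.49,
        "miR-301a-3p": 0.49,
    },
    "serous": {
        "miR-9-3p": 4.26,
        "miR-125b-5p": 1.67,
        "miR-638": 0.47,
    },
    "clear_cell": {
        "miR-375": 4.05,
        "miR-638": 2.39,
        "miR-1915-3p": 2.43,
        "miR-663a": 1.99,
        "miR-1246": 1.70,
        "miR-608": 1.69,
        "miR-612": 1.68,
        "miR-363-5p": 1.59,
        "miR-765": 1.58,
        "miR-1290": 1.53,
        "miR-135b-5p": 0.37,
        "miR-30a-3p": 0.43,
        "miR-135a-5p": 0.44,
    },
    "dedifferentiated": {
        "miR-449a": 9.68,
        "miR-449b-5p": 8.30,
        "miR-449c-5p": 5.28,
        "miR-205-5p": 2.99,
        "miR-10a-5p": 2.16,
        "miR-96-5p": 2.00,
        "miR-182-5p": 1.83,
        "miR-335-5p": 1.62,
        "miR-638": 0.45,
        "miR-612": 0.45,
        "miR-663a": 0.47,
    },
}

# Molecular subtypes (TCGA surrogates): effects are weaker than between
# histological subtypes; the MMR-deficient column never leaves (0.5, 1.5).
MOLECULAR_FOLD_CHANGES: dict[str, dict[str, float]] = {
    "MMRd": {
        "miR-483-3p": 1.34,
        "miR-885-5p": 1.37,
        "miR-1915-3p": 1.37,
        "miR-564": 1.32,
        "miR-196a-5p": 1.29,
        "miR-16-5p": 1.24,
        "miR-142-5p": 0.73,
        "miR-301a-3p": 0.77,
    },
    "POLE": {
        "miR-139-5p": 1.60,
        "miR-342-3p": 1.44,
        "miR-374b-5p": 1.36,
        "miR-515-5p": 0.31,
        "miR-210-3p": 0.49,
        "miR-885-3p": 0.55,
        "miR-612": 0.55,
        "miR-613": 0.55,
    },
    "p53abn": {
        "miR-34c-5p": 2.04,
        "miR-133b": 1.53,
        "miR-497-5p": 1.43,
        "miR-143-3p": 1.43,
        "miR-145-5p": 1.43,
        "miR-31-5p": 0.30,
        "miR-31-3p": 0.40,
        "miR-592": 0.58,
    },
    "p53wt": {
        "miR-205-5p": 2.07,
        "miR-200a-3p": 1.51,
        "miR-497-5p": 1.47,
        "miR-141-3p": 1.45,
        "miR-195-5p": 1.35,
        "miR-31-5p": 0.34,
        "miR-592": 0.52,
        "miR-1246": 0.68,
    },
}

# CTNNB1 exon-3 mutated tumors vs wildtype-sequenced tumors.
CTNNB1_FOLD_CHANGES: dict[str, dict[str, float]] = {
    "mutated": {
        "miR-203a-3p": 1.71,
        "miR-15a-5p": 1.29,
        "miR-16-5p": 1.25,
        "miR-499a-5p": 0.47,
        "miR-184": 0.56,
        "miR-342-5p": 0.58,
        "miR-135a-5p": 0.58,
    },
}

_BY_VARIABLE = {
    "histology": HISTOLOGY_FOLD_CHANGES,
    "molecular": MOLECULAR_FOLD_CHANGES,
    "ctnnb1": CTNNB1_FOLD_CHANGES,
}


def catalog_fold_changes(variable: str, level: str) -> dict[str, float]:
    """Reference fold changes for one subtype level (copy, safe to mutate)."""
    try:
        return dict(_BY_VARIABLE[variable][level])
    except KeyError:
        raise KeyError(f"no reference catalogue for {variable}={level}") from None
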