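"""Synthetic Ct-domain cohorts with planted subtype-specific fold changes.

The generator emulates a 384-well RT-qPCR panel study of endometrial
carcinoma: 352 miRNA assays plus 32 spike-in controls measured on 119
tumors (89 endometrioid / 8 serous / 13 clear cell / 9 de-differentiated),
of which 102 carry a molecular subtype label (48 MMRd / 8 POLE / 35 p53
wild type / 11 p53 abnormal) and 92 a CTNNB1 sequencing result (19
mutated).  Every quantity is drawn in the log2/Ct domain:

* each miRNA gets a baseline log2 level relative to the spike-ins, so raw
  Cts center on ``baseline_ct_mean`` (default 28 cycles);
* planted effects add ``log2(fold_change)`` to every sample of the target
  group, giving the downstream screen a known truth to recover;
* biological noise is Gaussian per sample within group (``noise_sd`` log2
  units) — log-normal on the linear scale, which is what makes the
  pooled-variance t-test well specified here;
* a per-sample technical shift (``sample_shift_sd`` cycles) moves all
  assays of a sample, spike-ins included, and must cancel under spike-in
  normalization;
* Cts at or beyond the detection limit are emitted as missing, producing
  realistic detection-limit censoring of lowly expressed miRNAs.

Generation is a pure function of the config (seed included): the same
config yields byte-identical TSV outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from . import catalog
from .cohort import (
    CT_MAX,
    CT_MIN,
    GRADE_LEVELS,
    UNKNOWN,
    RawCtMatrix,
    annotation_levels,
    validate_annotations,
)
from .screen import ScreenResult

__all__ = [
    "ConfigError",
    "PlantedEffect",
    "SyntheticCohortConfig",
    "default_effect_catalog",
    "generate_cohort",
    "effect_recovery_report",
]

SPIKE_PREFIX = "SPIKE_"

#: fraction of CTNNB1-mutated tumors with endometrioid histology (17 of 19)
_CTNNB1_ENDOMETRIOID_FRAC = 17.0 / 19.0

#: grade mix of endometrioid tumors (G1:G2:G3 = 33:33:23)
_GRADE_WEIGHTS = (33, 33, 23)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class PlantedEffect:
    """A known group-specific expression change: target group vs all others."""

    mirna_id: str
    variable: str
    level: str
    fold_change: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ConfigError(
                f"fold change must be positive, got {self.fold_change} for {self.mirna_id}"
            )


def default_effect_catalog() -> tuple[PlantedEffect, ...]:
    """The shipped planted-effect catalogue (reference subtype fold changes)."""
    effects = []
    for variable, table in (
        ("histology", catalog.HISTOLOGY_FOLD_CHANGES),
        ("molecular", catalog.MOLECULAR_FOLD_CHANGES),
        ("ctnnb1", catalog.CTNNB1_FOLD_CHANGES),
    ):
        for level, fcs in table.items():
            for mirna_id, fc in fcs.items():
                effects.append(PlantedEffect(mirna_id, variable, level, fc))
    return tuple(effects)


def _default_histology_sizes() -> dict[str, int]:
    return {"endometrioid": 89, "serous": 8, "clear_cell": 13, "dedifferentiated": 9}


def _default_molecular_sizes() -> dict[str, int]:
    return {"MMRd": 48, "POLE": 8, "p53wt": 35, "p53abn": 11}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Cohort design, planted truth, and noise model for one simulation."""

    n_mirnas: int = 352
    n_spikeins: int = 32
    histology_sizes: Mapping[str, int] = field(default_factory=_default_histology_sizes)
    molecular_sizes: Mapping[str, int] = field(default_factory=_default_molecular_sizes)
    ctnnb1_n_mutated: int = 19
    ctnnb1_n_known: int = 92
    effects: tuple[PlantedEffect, ...] = field(default_factory=default_effect_catalog)
    baseline_ct_mean: float = 28.0
    baseline_ct_sd: float = 2.0
    noise_sd: float = 1.0
    sample_shift_sd: float = 1.0
    detection_limit: float = 38.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "histology_sizes", dict(self.histology_sizes))
        object.__setattr__(self, "molecular_sizes", dict(self.molecular_sizes))
        object.__setattr__(
            self,
            "effects",
            tuple(
                e if isinstance(e, PlantedEffect) else PlantedEffect(**e) for e in self.effects
            ),
        )

    @property
    def n_samples(self) -> int:
        return sum(self.histology_sizes.values())

    def validate(self) -> None:
        if self.n_mirnas < 1 or self.n_spikeins < 1:
            raise ConfigError("need at least one miRNA and one spike-in assay")
        for name, sizes, levels in (
            ("histology_sizes", self.histology_sizes, annotation_levels("histology")),
            ("molecular_sizes", self.molecular_sizes, annotation_levels("molecular")),
        ):
            for level, n in sizes.items():
                if level not in levels:
                    raise ConfigError(f"{name}: unknown level {level!r}")
                if n < 0:
                    raise ConfigError(f"{name}: negative count for {level!r}")
        if self.n_samples < 1:
            raise ConfigError("cohort is empty")
        if sum(self.molecular_sizes.values()) > self.n_samples:
            raise ConfigError("molecular group sizes exceed the cohort size")
        if not (0 <= self.ctnnb1_n_mutated <= self.ctnnb1_n_known <= self.n_samples):
            raise ConfigError(
                "need 0 <= ctnnb1_n_mutated <= ctnnb1_n_known <= cohort size"
            )
        if self.noise_sd < 0 or self.baseline_ct_sd < 0 or self.sample_shift_sd < 0:
            raise ConfigError("standard deviations must be non-negative")
        if not (CT_MIN < self.detection_limit <= CT_MAX):
            raise ConfigError(f"detection limit must lie in ({CT_MIN:g}, {CT_MAX:g}]")
        seen = set()
        panel = set(self.mirna_ids())
        for e in self.effects:
            key = (e.mirna_id, e.variable, e.level)
            if key in seen:
                raise ConfigError(f"duplicate planted effect for {key}")
            seen.add(key)
            if e.level not in annotation_levels(e.variable):
                raise ConfigError(
                    f"planted effect on {e.mirna_id!r} references unknown "
                    f"{e.variable} level {e.level!r}"
                )
            if e.mirna_id not in panel:
                raise ConfigError(
                    f"planted effect references miRNA {e.mirna_id!r} not in the panel"
                )

    def mirna_ids(self) -> tuple[str, ...]:
        """Panel assay names: catalogue miRNAs first, then synthetic fillers."""
        named: list[str] = []
        seen: set[str] = set()
        for table in (
            catalog.HISTOLOGY_FOLD_CHANGES,
            catalog.MOLECULAR_FOLD_CHANGES,
            catalog.CTNNB1_FOLD_CHANGES,
        ):
            for fcs in table.values():
                for mid in fcs:
                    if mid not in seen:
                        named.append(mid)
                        seen.add(mid)
        named = named[: self.n_mirnas]
        fillers = [f"miR-sim-{k:03d}" for k in range(1, self.n_mirnas - len(named) + 1)]
        return tuple(named + fillers)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effects"] = [asdict(e) for e in self.effects]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticCohortConfig":
        d = dict(d)
        d["effects"] = tuple(
            PlantedEffect(**e) if isinstance(e, Mapping) else e for e in d.get("effects", ())
        )
        return cls(**d)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _largest_remainder(total: int, weights: tuple[int, ...]) -> list[int]:
    quotas = [total * w / sum(weights) for w in weights]
    counts = [int(q) for q in quotas]
    for _ in range(total - sum(counts)):
        i = max(range(len(quotas)), key=lambda k: quotas[k] - counts[k])
        counts[i] += 1
    return counts


def _assign_annotations(
    config: SyntheticCohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    n = config.n_samples
    sample_ids = [f"S{k:03d}" for k in range(1, n + 1)]
    histology = np.repeat(
        list(config.histology_sizes), list(config.histology_sizes.values())
    ).astype(object)

    grade = np.full(n, UNKNOWN, dtype=object)
    endo = np.flatnonzero(histology == "endometrioid")
    grade[endo] = np.repeat(GRADE_LEVELS, _largest_remainder(endo.size, _GRADE_WEIGHTS))

    molecular = np.full(n, UNKNOWN, dtype=object)
    n_typed = sum(config.molecular_sizes.values())
    typed = rng.choice(n, size=n_typed, replace=False)
    molecular[typed] = np.repeat(
        list(config.molecular_sizes), list(config.molecular_sizes.values())
    )

    ctnnb1 = np.full(n, UNKNOWN, dtype=object)
    sequenced = rng.choice(n, size=config.ctnnb1_n_known, replace=False)
    ctnnb1[sequenced] = "wildtype"
    # mutations land preferentially in endometrioid tumors (17 of 19)
    seq_endo = np.array([s for s in sequenced if histology[s] == "endometrioid"])
    seq_other = np.array([s for s in sequenced if histology[s] != "endometrioid"])
    n_mut_endo = min(round(_CTNNB1_ENDOMETRIOID_FRAC * config.ctnnb1_n_mutated), seq_endo.size)
    n_mut_other = min(config.ctnnb1_n_mutated - n_mut_endo, seq_other.size)
    n_mut_endo = min(config.ctnnb1_n_mutated - n_mut_other, seq_endo.size)
    if seq_endo.size:
        ctnnb1[rng.choice(seq_endo, size=n_mut_endo, replace=False)] = "mutated"
    if seq_other.size and n_mut_other:
        ctnnb1[rng.choice(seq_other, size=n_mut_other, replace=False)] = "mutated"

    ann = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "histology": histology,
            "grade": grade,
            "molecular": molecular,
            "ctnnb1": ctnnb1,
        }
    )
    return validate_annotations(ann)


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[RawCtMatrix, pd.DataFrame, tuple[PlantedEffect, ...]]:
    """Simulate one cohort; returns (raw Ct matrix, annotations, planted truth).

    Independent random streams are used for label assignment, baselines,
    biological noise, and technical shifts, so switching one component off
    (e.g. ``sample_shift_sd=0``) leaves the others' draws untouched.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_labels, rng_base, rng_noise, rng_shift = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    ann = _assign_annotations(config, rng_labels)
    n = config.n_samples
    mirna_ids = config.mirna_ids()
    spike_ids = tuple(f"{SPIKE_PREFIX}{k:02d}" for k in range(1, config.n_spikeins + 1))

    # spike-in base Cts cluster around 20 cycles; median exactly 20
    spike_base = np.linspace(19.0, 21.0, config.n_spikeins)
    spike_ref = float(np.median(spike_base))

    baseline = rng_base.normal(
        spike_ref - config.baseline_ct_mean, config.baseline_ct_sd, size=len(mirna_ids)
    )
    expr = baseline[:, None] + rng_noise.normal(0.0, config.noise_sd, (len(mirna_ids), n))

    row_of = {m: i for i, m in enumerate(mirna_ids)}
    for e in config.effects:
        members = (ann[e.variable] == e.level).to_numpy()
        expr[row_of[e.mirna_id], members] += np.log2(e.fold_change)

    shift = rng_shift.normal(0.0, config.sample_shift_sd, size=n)
    ct_mirna = spike_ref - expr + shift[None, :]
    ct_mirna[ct_mirna >= config.detection_limit] = np.nan
    ct_mirna = np.clip(ct_mirna, CT_MIN, CT_MAX)
    ct_spike = np.clip(spike_base[:, None] + shift[None, :], CT_MIN, CT_MAX)

    raw = RawCtMatrix(
        mirna_ids + spike_ids,
        tuple(ann["sample_id"]),
        np.vstack([ct_mirna, ct_spike]),
        frozenset(spike_ids),
    )
    return raw, ann, tuple(config.effects)


def effect_recovery_report(
    truth: tuple[PlantedEffect, ...] | list[PlantedEffect],
    screen: ScreenResult,
) -> pd.DataFrame:
    """Join planted truth to a screen of the same cohort, per effect.

    Only effects targeting the screen's own contrast (``variable=level`` in
    the contrast name) are joined.  An effect whose miRNA was dropped
    before testing (detection-limit censoring) appears with a missing
    estimate and ``detected=False``.
    """
    variable, _, level = screen.contrast_name.partition("=")
    relevant = [e for e in truth if e.variable == variable and e.level == level]
    by_mirna = {r.mirna_id: r for r in screen.records}
    rows = []
    for e in relevant:
        rec = by_mirna.get(e.mirna_id)
        rows.append(
            {
                "mirna_id": e.mirna_id,
                "variable": e.variable,
                "level": e.level,
                "true_fc": e.fold_change,
                "estimated_fc": rec.fold_change if rec else np.nan,
                "perm_p": rec.perm_p if rec else np.nan,
                "detected": bool(rec and rec.perm_p < screen.alpha),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id", "variable", "level", "true_fc", "estimated_fc", "perm_p", "detected",
        ],
    )
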