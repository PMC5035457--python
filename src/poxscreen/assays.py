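"""Quantitative wet-lab follow-up procedures.

Small, exactly specified computations used when validating knockout
mutants: relative expression by the comparative-Ct (2^-ddCt) method,
reducing-sugar / p-nitrophenol enzyme activity units, percent change
with a two-tailed Student's t test, and conversion of intracellular
protein to biomass dry weight.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


class AssayError(ValueError):
    pass


def relative_expression(
    target_test: list[float],
    control_test: list[float],
    target_ref: list[float],
    control_ref: list[float],
) -> float:
    """Comparative-Ct fold change of the test strain over the reference.

    dCt = Ct_target - Ct_control per matched replicate; ddCt is the
    difference of the strain means; the fold change assumes a doubling
    per cycle (amplification efficiency 2).
    """
    if len(target_test) != len(control_test) or len(target_ref) != len(control_ref):
        raise AssayError("target and control-gene Ct lists must be matched")
    if not target_test or not target_ref:
        raise AssayError("missing control or reference measurements")
    dct_test = [t - c for t, c in zip(target_test, control_test)]
    dct_ref = [t - c for t, c in zip(target_ref, control_ref)]
    ddct = float(np.mean(dct_test) - np.mean(dct_ref))
    return 2.0 ** (-ddct)


@dataclass
class EnzymeAssay:
    """One reducing-sugar or pNP release measurement.

    One enzyme unit produces 1 umol of product (glucose, xylose or
    p-nitrophenol depending on the substrate) per minute.
    """

    substrate: str  # FPase / CMCase / xylanase / pNPCase / pNPGase / Avicelase / KSBase
    product_umol: float
    reaction_minutes: float
    enzyme_volume_ml: float
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.reaction_minutes <= 0 or self.enzyme_volume_ml <= 0:
            raise AssayError("reaction time and enzyme volume must be positive")
        if self.product_umol < 0 or self.dilution_factor < 1:
            raise AssayError("product must be >= 0 and dilution factor >= 1")


def enzyme_units(assay: EnzymeAssay) -> float:
    """Volumetric activity in U/mL."""
    return (
        assay.product_umol
        / assay.reaction_minutes
        / assay.enzyme_volume_ml
        * assay.dilution_factor
    )


def percent_change_test(
    group_a: list[float], group_b: list[float], equal_var: bool = True
) -> tuple[float, float, float]:
    """Percent change of B relative to A with a two-tailed two-sample t test.

    Pooled-variance Student's t by default (``equal_var=False`` for
    Welch).  Returns (percent_change, t, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise AssayError("need at least two replicates per group")
    if a.mean() == 0:
        raise AssayError("group A mean is zero; percent change undefined")
    pct = (b.mean() - a.mean()) / a.mean() * 100.0
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return pct, 0.0, 1.0
        logger.warning("zero variance with unequal means; p below machine floor")
        return pct, math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return pct, float(t), float(p)


@dataclass
class BiomassConstant:
    """Grams of intracellular protein per gram of dry cell mass."""

    protein_per_dry_mass: float = 0.28

    def __post_init__(self) -> None:
        if not 0 < self.protein_per_dry_mass <= 1:
            raise AssayError("protein/dry-mass constant must be in (0, 1]")


def biomass_from_protein(
    protein_g_per_l: float, c: BiomassConstant | None = None
) -> float:
    """Dry weight (g/L) inferred from intracellular protein (g/L)."""
    if protein_g_per_l < 0:
        raise AssayError("protein concentration must be >= 0")
    c = c or BiomassConstant()
    return protein_g_per_l / c.protein_per_dry_mass
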