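"""Parameter containers for the allocation model and Monod kinetics.

The allocation model describes a phytoplankton cell as a set of
macromolecular pools expressed as quotas (mol C or mol N per mol cell C).
``CfmParams`` collects the physiological constants of that description plus
the two parameters that are fitted to growth data: ``A_pho`` (photosynthetic
protein to chlorophyll mass ratio) and ``A_N`` (nitrate uptake affinity).

Units are fixed throughout the package: concentrations in µM, rates in
day⁻¹, quotas in mol per mol cell C, irradiance in µmol photons m⁻² s⁻¹.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

from .errors import InfeasibleParametersError

#: Protein C:N molar ratio; proteins carry one N per 4.49 C on average.
PROTEIN_C_TO_N = 4.49


@dataclass(frozen=True)
class CfmParams:
    """Physiological constants of the macromolecular allocation model.

    Parameters
    ----------
    P_max_chl
        Maximum C-fixation rate per mol chlorophyll C (day⁻¹).
    O_I
        Irradiance saturation coefficient ((µmol photons m⁻² s⁻¹)⁻¹);
        photosynthesis saturates as ``1 - exp(-O_I * I)``.
    I
        Irradiance of the experiment (µmol photons m⁻² s⁻¹).
    E
        Excretion/biosynthetic cost fraction: fixing enough C to grow at
        rate mu costs ``mu * (1 + E)`` in gross fixation (dimensionless).
    m
        Maintenance respiration rate (day⁻¹), an extra gross-fixation demand.
    A_pho
        Photosynthetic protein C : chlorophyll C mass ratio (dimensionless).
        One of the two fitted parameters.
    A_plip
        Thylakoid-membrane lipid C : chlorophyll C ratio (dimensionless).
    k_bio
        Biosynthetic protein C quota per unit growth rate (day).
    r_bio_pho
        Fixed ratio ``A_pho / k_bio`` used to slave ``k_bio`` to ``A_pho``
        during fitting (dimensionless).
    Q_pro_ess_C
        Essential (growth-independent) protein C quota.
    A_rna
        RNA C per protein C per unit growth rate (day); encodes the linear
        RNA–protein–growth coupling.
    Q_rna_min_C
        Minimum RNA C quota at zero growth.
    Q_dna_C, Q_oth_C
        Constant DNA and "other essential C" quotas (carbohydrate and
        remaining structural C are folded into the latter).
    Q_nsto_C
        C quota of the N-storage pool when N is replete.
    Y_pro_NC, Y_rna_NC, Y_dna_NC, Y_chl_NC, Y_nsto_NC
        N:C stoichiometric ratios of the N-bearing pools (mol N / mol C).
    A_N
        Nitrate uptake affinity (mol N (mol cell C)⁻¹ day⁻¹ µM⁻¹); uptake is
        ``A_N * [NO3⁻]``. The second fitted parameter.
    """

    P_max_chl: float = 7.0
    O_I: float = 0.01
    I: float = 200.0
    E: float = 0.2
    m: float = 0.05
    A_pho: float = 3.56
    A_plip: float = 0.12
    k_bio: float = 0.25
    r_bio_pho: float = 3.56 / 0.25
    Q_pro_ess_C: float = 0.12
    A_rna: float = 0.2
    Q_rna_min_C: float = 0.005
    Q_dna_C: float = 0.005
    Q_oth_C: float = 0.08
    Q_nsto_C: float = 0.0
    Y_pro_NC: float = 1.0 / PROTEIN_C_TO_N
    Y_rna_NC: float = 0.395
    Y_dna_NC: float = 0.385
    Y_chl_NC: float = 4.0 / 55.0
    Y_nsto_NC: float = 0.45
    A_N: float = 0.02

    _POSITIVE = ("P_max_chl", "O_I", "A_pho", "k_bio", "r_bio_pho",
                 "Y_pro_NC", "Y_rna_NC", "Y_dna_NC", "Y_chl_NC",
                 "Y_nsto_NC", "A_N")
    _NONNEGATIVE = ("I", "E", "m", "A_plip", "Q_pro_ess_C", "A_rna",
                    "Q_rna_min_C", "Q_dna_C", "Q_oth_C", "Q_nsto_C")

    def __post_init__(self) -> None:
        for name in self._POSITIVE:
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InfeasibleParametersError(
                    f"parameter {name} must be finite and > 0, got {v!r}")
        for name in self._NONNEGATIVE:
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise InfeasibleParametersError(
                    f"parameter {name} must be finite and >= 0, got {v!r}")

    def replace(self, **changes: float) -> "CfmParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def with_fitted(self, A_pho: float, A_N: float) -> "CfmParams":
        """Copy with new fitted parameters, keeping k_bio slaved to A_pho."""
        return self.replace(A_pho=A_pho, A_N=A_N, k_bio=A_pho / self.r_bio_pho)


@dataclass(frozen=True)
class MonodParams:
    """Monod kinetics parameters: mu_max (day⁻¹) and half-saturation Ks (µM)."""

    mu_max: float
    Ks: float

    def __post_init__(self) -> None:
        for name in ("mu_max", "Ks"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InfeasibleParametersError(
                    f"parameter {name} must be finite and > 0, got {v!r}")
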