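"""Physical constants for the resistance network and air thermodynamics."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants of the big-leaf resistance network.

    Diffusivities are in cm^2 s^-1 as conventionally tabulated; the
    quasi-laminar resistance uses only their ratios so the unit cancels.
    """

    k: float = 0.4                  #: von Karman constant
    kappa_heat: float = 0.2         #: thermal diffusivity of air, cm^2 s^-1
    D_o3: float = 0.14              #: molecular diffusivity of O3 in air, cm^2 s^-1
    D_h2o: float = 0.249            #: molecular diffusivity of H2O in air, cm^2 s^-1
    D_ratio_o3_h2o: float = 0.61    #: ratio of O3 to H2O diffusivity (stomatal path)
    g: float = 9.81                 #: gravitational acceleration, m s^-2
    R_gas: float = 8.314            #: universal gas constant, J mol^-1 K^-1
    M_h2o: float = 0.018015         #: molar mass of water, kg mol^-1
    Rd: float = 287.05              #: specific gas constant, dry air, J kg^-1 K^-1
    Rv: float = 461.5               #: specific gas constant, water vapor, J kg^-1 K^-1
    cp_dry: float = 1004.0          #: specific heat of dry air, J kg^-1 K^-1
    T0: float = 273.15              #: 0 degC in K

    def __post_init__(self) -> None:
        for name in ("k", "kappa_heat", "D_o3", "D_h2o", "g", "R_gas"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.D_ratio_o3_h2o < 1.0:
            raise ValueError("D_ratio_o3_h2o must lie in (0, 1)")


CONST = PhysicalConstants()
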