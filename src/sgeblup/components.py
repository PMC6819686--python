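"""Variance-component containers shared by the simulator, REML engine and evaluation."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class VarianceComponents:
    """(Co)variance components of the direct-social animal model, in (g/d)^2.

    sigma2_aD   direct additive genetic variance
    sigma_aDaS  covariance between direct and social genetic effects
    sigma2_aS   social (indirect) genetic variance
    sigma2_g    non-genetic group (pen) variance
    sigma2_l    birth-litter variance
    sigma2_e    residual variance
    """

    sigma2_aD: float
    sigma_aDaS: float = 0.0
    sigma2_aS: float = 0.0
    sigma2_g: float = 0.0
    sigma2_l: float = 0.0
    sigma2_e: float = 1.0

    def C(self) -> np.ndarray:
        """The 2x2 direct-social genetic covariance matrix."""
        return np.array(
            [[self.sigma2_aD, self.sigma_aDaS], [self.sigma_aDaS, self.sigma2_aS]]
        )

    def validate(self, psd_tol: float = 1e-9) -> None:
        for name in ("sigma2_aD", "sigma2_aS", "sigma2_g", "sigma2_l", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        C = self.C()
        scale = max(np.trace(C), 1.0)
        if np.linalg.eigvalsh(C).min() < -psd_tol * scale:
            raise ValueError(
                "direct-social covariance matrix C = "
                f"[[{self.sigma2_aD}, {self.sigma_aDaS}], "
                f"[{self.sigma_aDaS}, {self.sigma2_aS}]] is not positive semidefinite"
            )

    def as_array(self, social: bool = True) -> np.ndarray:
        if social:
            return np.array(
                [self.sigma2_aD, self.sigma_aDaS, self.sigma2_aS,
                 self.sigma2_g, self.sigma2_l, self.sigma2_e]
            )
        return np.array([self.sigma2_aD, self.sigma2_g, self.sigma2_l, self.sigma2_e])

    @staticmethod
    def from_array(theta: np.ndarray, social: bool = True) -> "VarianceComponents":
        theta = np.asarray(theta, dtype=float)
        if social:
            return VarianceComponents(*theta)
        return VarianceComponents(
            sigma2_aD=theta[0], sigma2_g=theta[1], sigma2_l=theta[2], sigma2_e=theta[3]
        )

    def replace(self, **kw) -> "VarianceComponents":
        return replace(self, **kw)
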