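"""Two-step MR mediation: indirect effect, proportion mediated, screens.

The mediation chain exposure -> mediator -> outcome is quantified by the
product of coefficients: ``indirect = beta_xm * beta_my`` with
``proportion = indirect / beta_total``, where

* ``beta_total`` is the univariable IVW estimate of the exposure on the
  outcome (the total effect),
* ``beta_xm`` the IVW estimate of the exposure on the mediator (exposure
  instruments), and
* ``beta_my`` the mediator-on-outcome effect using the mediator's own
  instruments — by default estimated by multivariable IVW adjusting for the
  exposure, which identifies the mediator's direct effect when mediator
  instruments also perturb the exposure pathway (a univariable IVW variant
  is available via ``adjust_exposure=False``).

The delta-method SE of the indirect effect is
``sqrt(beta_xm^2 se_my^2 + beta_my^2 se_xm^2)``.  A combination is reported
as mediating only when the direction screen passes: the sign of the
indirect effect must agree with the sign of the total effect (an exactly
zero indirect effect counts as consistent with proportion 0).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .estimators import MREstimate, ivw_from_hset, mvmr_ivw
from .instruments import IVConfig, LDMatrix
from .sumstats import harmonize

__all__ = ["MediationResult", "StepFailure", "two_step_mediation",
           "direction_screen", "reverse_mr", "reverse_pass"]


class StepFailure(RuntimeError):
    """A mediation step had no usable instruments; the message names it."""


@dataclasses.dataclass
class MediationResult:
    """Product-of-coefficients mediation decomposition with audit trail.

    ``proportion`` is on the fraction scale (``proportion_pct`` in percent),
    unclipped: it may exceed 1 or be negative when the direction screen is
    off.  The identity ``indirect == total.beta * 0 + xm.beta * my.beta``
    holds exactly by construction.
    """

    total: MREstimate
    xm: MREstimate
    my: MREstimate
    indirect: float
    se_indirect: float
    direction_consistent: bool
    zero_total: bool = False
    reverse_pval: float | None = None

    @property
    def beta_total(self) -> float:
        return self.total.beta

    @property
    def proportion(self) -> float:
        if self.zero_total:
            return float("nan")
        return self.indirect / self.total.beta

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.proportion

    def as_row(self) -> dict:
        return {
            "beta_total": self.total.beta, "se_total": self.total.se,
            "beta_xm": self.xm.beta, "beta_my": self.my.beta,
            "indirect": self.indirect, "se_indirect": self.se_indirect,
            "proportion_pct": self.proportion_pct,
            "direction_pass": self.direction_consistent,
            "reverse_pval": self.reverse_pval,
        }


def _select_or_fail(step: str, records: pd.DataFrame, ld, iv: IVConfig) -> pd.DataFrame:
    chosen = iv.select(records, ld).records
    if len(chosen) == 0:
        raise StepFailure(f"no usable instruments at step '{step}'")
    return chosen


def two_step_mediation(
    exposure: pd.DataFrame,
    mediator: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: LDMatrix | None = None,
    iv: IVConfig | None = None,
    adjust_exposure: bool = True,
) -> MediationResult:
    """Estimate total, exposure->mediator, and mediator->outcome effects.

    Instruments are selected independently for the exposure and the mediator
    via the IV chain in ``iv`` (defaults: p < 5e-6, r^2 < 0.001 / 10,000 kb,
    F >= 10).  Raises :class:`StepFailure` naming the step when a selection
    or harmonization yields nothing usable.
    """
    iv = iv or IVConfig()

    exp_iv = _select_or_fail("exposure_instruments", exposure, ld, iv)
    h_xo = harmonize(exp_iv, outcome)
    if h_xo.n_snp == 0:
        raise StepFailure("no harmonized SNPs at step 'exposure->outcome'")
    total = ivw_from_hset(*h_xo.arrays())

    h_xm = harmonize(exp_iv, mediator)
    if h_xm.n_snp == 0:
        raise StepFailure("no harmonized SNPs at step 'exposure->mediator'")
    xm = ivw_from_hset(*h_xm.arrays())

    med_iv = _select_or_fail("mediator_instruments", mediator, ld, iv)
    h_my = harmonize(med_iv, outcome, mediator=exposure)
    if h_my.n_snp == 0:
        raise StepFailure("no harmonized SNPs at step 'mediator->outcome'")
    if adjust_exposure and h_my.n_snp >= 4:
        X = np.column_stack([h_my.df["gamma_x"].to_numpy(),
                             h_my.df["gamma_m"].to_numpy()])
        my = mvmr_ivw(X, h_my.df["gamma_y"].to_numpy(),
                      h_my.df["se_y"].to_numpy(),
                      names=["mediator", "exposure"])[0]
    else:
        my = ivw_from_hset(*h_my.arrays())

    indirect = xm.beta * my.beta
    se_indirect = float(np.sqrt(xm.beta**2 * my.se**2 + my.beta**2 * xm.se**2))
    result = MediationResult(total=total, xm=xm, my=my, indirect=indirect,
                             se_indirect=se_indirect,
                             direction_consistent=False,
                             zero_total=(total.beta == 0))
    result.direction_consistent = direction_screen(result)
    return result


def direction_screen(result: MediationResult) -> bool:
    """True iff the indirect effect's sign agrees with the total effect's.

    A zero total effect fails the screen (flagged via ``zero_total``); an
    exactly zero indirect effect passes (degenerate, proportion 0) so exact
    nulls are not spuriously excluded.
    """
    if result.total.beta == 0:
        return False
    if result.indirect == 0:
        return True
    return bool(np.sign(result.indirect) == np.sign(result.total.beta))


def reverse_mr(
    outcome_as_exposure: pd.DataFrame,
    exposure_as_outcome: pd.DataFrame,
    ld: LDMatrix | None = None,
    iv: IVConfig | None = None,
) -> MREstimate:
    """Reverse-causation check: rerun IVW with the trait roles swapped.

    Instruments are selected for the original outcome trait; swapping twice
    reproduces the forward analysis exactly.
    """
    iv = iv or IVConfig()
    rev_iv = _select_or_fail("reverse_instruments", outcome_as_exposure, ld, iv)
    h = harmonize(rev_iv, exposure_as_outcome)
    if h.n_snp == 0:
        raise StepFailure("no harmonized SNPs at step 'reverse'")
    return ivw_from_hset(*h.arrays())


def reverse_pass(estimate: MREstimate, alpha: float = 0.05) -> bool:
    """The reverse-MR screen passes when the reverse IVW p is >= alpha."""
    return estimate.pval >= alpha
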