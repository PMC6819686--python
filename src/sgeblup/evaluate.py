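"""Breeding-value evaluation: BLUP solutions, PEV, derived genetic parameters,
theoretical accuracies and forward cross-validation.

Total and combined breeding values follow the social-effects bookkeeping:

    TBV_i = a_D,i + (n - 1) a_S,i          (heritable impact on the population)
    CBV_i = a_D,i + sum over pen mates j of a_S,j   (impact on own record)

with n the average group size of the phenotyped records.  Theoretical
accuracy of an estimated effect is R = sqrt(1 - PEV / ((1 + F) sigma^2)),
PEV read from the inverted mixed-model coefficient matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .components import VarianceComponents
from .design import DesignMatrices, SocialModelSpec, build_design
from .pedigree import PedigreeTable
from .reml import GeneticKernel, MixedModelSystem

logger = logging.getLogger(__name__)

__all__ = [
    "MMESolution",
    "EvaluationResult",
    "solve_mme",
    "total_breeding_value",
    "combined_breeding_value",
    "total_heritable_variance",
    "phenotypic_variance",
    "total_heritability",
    "genetic_correlation",
    "theoretical_accuracy",
    "evaluate_model",
    "forward_validation",
]


@dataclass
class MMESolution:
    """BLUE/BLUP solutions of one model at fixed variance components."""

    fixed: pd.Series              # named fixed-effect estimates
    dbv: np.ndarray               # a_D-hat per pedigree animal
    sbv: np.ndarray | None        # a_S-hat per pedigree animal (social models)
    litter: np.ndarray | None
    group: np.ndarray | None
    pev_D: np.ndarray             # diag of the a_D block of the inverse MME
    pev_S: np.ndarray | None
    animal_ids: np.ndarray


def solve_mme(
    design: DesignMatrices,
    kernel: GeneticKernel,
    components: VarianceComponents,
    spec: SocialModelSpec,
) -> MMESolution:
    """Solve Henderson's MME at the given components; PEV from the inverse."""
    sys_ = MixedModelSystem(design, kernel, spec)
    theta = sys_.theta(components)
    cho, _ = sys_.factorize(theta)
    _, _, s_e = sys_._scalars(theta)
    sol = sys_.solve(cho, sys_.Wty / s_e)
    Minv = sys_._inverse(cho)
    m = sys_.m
    dbv = sol[sys_.off_g : sys_.off_g + m]
    pev_D = np.diag(Minv)[sys_.off_g : sys_.off_g + m].copy()
    sbv = pev_S = None
    if spec.include_social:
        sbv = sol[sys_.off_g + m : sys_.off_g + 2 * m]
        pev_S = np.diag(Minv)[sys_.off_g + m : sys_.off_g + 2 * m].copy()
    litter = sol[sys_.off_l : sys_.off_l + sys_.L] if sys_.L else None
    group = sol[sys_.off_v : sys_.off_v + sys_.P] if sys_.P else None
    return MMESolution(
        fixed=pd.Series(sol[: sys_.p], index=sys_.fixed_names),
        dbv=dbv,
        sbv=sbv,
        litter=litter,
        group=group,
        pev_D=pev_D,
        pev_S=pev_S,
        animal_ids=design.animal_ids,
    )


def total_breeding_value(dbv: np.ndarray, sbv: np.ndarray | None, n: float) -> np.ndarray:
    """TBV = DBV + (n - 1) SBV; reduces to DBV for n = 1 or a classic model."""
    if n < 1:
        raise ValueError(f"group size must be >= 1, got {n}")
    if sbv is None:
        return np.asarray(dbv, dtype=float).copy()
    return np.asarray(dbv, dtype=float) + (n - 1.0) * np.asarray(sbv, dtype=float)


def combined_breeding_value(
    dbv_by_animal: dict,
    sbv_by_animal: dict | None,
    pen_membership: pd.DataFrame,
) -> pd.Series:
    """CBV_i = own DBV + sum of pen mates' SBV.

    pen_membership needs columns (animal, pen).  Animals without a pen (or
    under a classic model) get CBV = DBV.
    """
    pens = pen_membership.groupby("pen")["animal"].apply(list).to_dict()
    pen_of = dict(zip(pen_membership.animal, pen_membership.pen))
    out = {}
    for a in pen_membership.animal:
        cbv = dbv_by_animal[a]
        if sbv_by_animal is not None:
            pen = pen_of.get(a)
            if pen is None:
                logger.warning("animal %r has no pen; CBV falls back to DBV", a)
            else:
                cbv += sum(sbv_by_animal[m] for m in pens[pen] if m != a)
        out[a] = cbv
    return pd.Series(out, name="CBV")


def total_heritable_variance(components: VarianceComponents, n: float) -> float:
    """sigma2_TBV = s2_aD + 2 (n-1) s_aDaS + (n-1)^2 s2_aS."""
    if n < 1:
        raise ValueError(f"group size must be >= 1, got {n}")
    c = components
    return c.sigma2_aD + 2.0 * (n - 1.0) * c.sigma_aDaS + (n - 1.0) ** 2 * c.sigma2_aS


def phenotypic_variance(components: VarianceComponents, n: float) -> float:
    """sigma2_P = s2_aD + (n-1) s2_aS + s2_g + s2_l + s2_e."""
    if n < 1:
        raise ValueError(f"group size must be >= 1, got {n}")
    c = components
    return c.sigma2_aD + (n - 1.0) * c.sigma2_aS + c.sigma2_g + c.sigma2_l + c.sigma2_e


def total_heritability(components: VarianceComponents, n: float) -> float:
    """T^2 = sigma2_TBV / sigma2_P; can exceed 1 for large groups."""
    s2p = phenotypic_variance(components, n)
    if s2p <= 0:
        raise ValueError("phenotypic variance is zero; T^2 undefined")
    return total_heritable_variance(components, n) / s2p


def genetic_correlation(components: VarianceComponents) -> float:
    """r = s_aDaS / sqrt(s2_aD s2_aS) between direct and social effects."""
    c = components
    if c.sigma2_aD <= 0 or c.sigma2_aS <= 0:
        raise ValueError("genetic correlation undefined with a zero variance")
    r = c.sigma_aDaS / np.sqrt(c.sigma2_aD * c.sigma2_aS)
    return float(np.clip(r, -1.0, 1.0))


def theoretical_accuracy(
    pev: np.ndarray, F: np.ndarray, sigma2: float
) -> np.ndarray:
    """R = sqrt(1 - PEV / ((1 + F) sigma^2)), clipped to 0 on numerical excess."""
    if sigma2 <= 0:
        raise ValueError("genetic variance must be positive for accuracies")
    denom = (1.0 + np.asarray(F, dtype=float)) * sigma2
    ratio = np.asarray(pev, dtype=float) / denom
    excess = ratio > 1.0
    if excess.any():
        logger.warning(
            "PEV exceeds (1+F) sigma^2 for %d animals (max excess %.3g); accuracy clipped to 0",
            int(excess.sum()), float(ratio.max() - 1.0),
        )
    return np.sqrt(np.clip(1.0 - ratio, 0.0, None))


@dataclass
class EvaluationResult:
    """Per-animal breeding values/accuracies plus model-level genetic parameters."""

    per_animal: pd.DataFrame
    components: VarianceComponents
    n_bar: float
    r: float | None
    sigma2_TBV: float
    sigma2_P: float
    T2: float
    model_label: str
    cv_correlation: float | None = None


def evaluate_model(
    phenotypes: pd.DataFrame,
    pedigree: PedigreeTable,
    kernel: GeneticKernel,
    components: VarianceComponents,
    spec: SocialModelSpec,
    model_label: str = "model",
) -> EvaluationResult:
    """Solve the model and tabulate DBV/SBV/TBV/CBV/PEV/accuracies per animal."""
    design = build_design(phenotypes, pedigree, spec)
    solution = solve_mme(design, kernel, components, spec)
    n_bar = design.avg_group_size
    ids = solution.animal_ids
    dbv_map = dict(zip(ids, solution.dbv))
    sbv_map = dict(zip(ids, solution.sbv)) if solution.sbv is not None else None
    tbv = total_breeding_value(solution.dbv, solution.sbv, n_bar)
    cbv = combined_breeding_value(dbv_map, sbv_map, phenotypes[["animal", "pen"]])
    R_D = theoretical_accuracy(solution.pev_D, pedigree.F, components.sigma2_aD)
    social = spec.include_social
    table = pd.DataFrame({
        "animal": ids,
        "DBV": solution.dbv,
        "SBV": solution.sbv if social else np.nan,
        "TBV": tbv,
        "PEV_D": solution.pev_D,
        "R_D": R_D,
    })
    if social and components.sigma2_aS > 0:
        table["PEV_S"] = solution.pev_S
        table["R_S"] = theoretical_accuracy(
            solution.pev_S, pedigree.F, components.sigma2_aS
        )
    table = table.merge(cbv.rename("CBV"), left_on="animal", right_index=True, how="left")
    table["CBV"] = table.CBV.fillna(table.DBV)
    table["phenotyped"] = table.animal.isin(phenotypes.animal)
    r = None
    if social and components.sigma2_aS > 0 and components.sigma2_aD > 0:
        r = genetic_correlation(components)
    return EvaluationResult(
        per_animal=table,
        components=components,
        n_bar=n_bar,
        r=r,
        sigma2_TBV=total_heritable_variance(components, n_bar if social else 1.0),
        sigma2_P=phenotypic_variance(components, n_bar if social else 1.0),
        T2=total_heritability(components, n_bar if social else 1.0),
        model_label=model_label,
    )


def forward_validation(
    phenotypes: pd.DataFrame,
    pedigree: PedigreeTable,
    kernel: GeneticKernel,
    components: VarianceComponents,
    spec: SocialModelSpec,
    n_masked_periods: int = 2,
):
    """Forward cross-validation: mask the last periods, predict their records.

    Training = all records except the last ``n_masked_periods`` distinct
    values of the ``period`` column.  The model is solved on the training
    records only (validation animals stay in the pedigree/H), fixed-effect
    estimates are applied to the validation records to give the corrected
    phenotype y_c = y - X b-hat, and the returned statistic is the Pearson
    correlation between CBV and y_c over validation animals.

    Fixed-effect levels seen only in the validation period (future batches)
    are inestimable from training; their columns are dropped, so those
    records are corrected by the intercept and the shared effects only.
    """
    periods = np.sort(phenotypes.period.unique())
    if len(periods) < n_masked_periods + 1:
        raise ValueError(
            f"need more than {n_masked_periods} periods for forward validation, "
            f"got {len(periods)}"
        )
    masked = set(periods[-n_masked_periods:])
    is_val = phenotypes.period.isin(masked).to_numpy()
    if not is_val.any() or is_val.all():
        raise ValueError("forward split produced an empty training or validation set")

    full_design = build_design(phenotypes, pedigree, spec)
    train_rows = np.where(~is_val)[0]
    val_rows = np.where(is_val)[0]

    X_full = full_design.X
    support = np.asarray(
        (X_full[train_rows] != 0).sum(axis=0)
    ).ravel() > 0
    X_kept = X_full[:, support]
    kept_names = [n for n, s in zip(full_design.fixed_names, support) if s]

    def rows(mat, r):
        return mat[r] if mat is not None else None

    train_design = replace(
        full_design,
        X=X_kept[train_rows],
        Z_D=full_design.Z_D[train_rows],
        Z_S=rows(full_design.Z_S, train_rows),
        W=rows(full_design.W, train_rows),
        V=rows(full_design.V, train_rows),
        y=full_design.y[train_rows],
        fixed_names=kept_names,
        record_animals=full_design.record_animals[train_rows],
        group_sizes=full_design.group_sizes[train_rows],
        pen_of_record=full_design.pen_of_record[train_rows],
    )
    solution = solve_mme(train_design, kernel, components, spec)

    # corrected phenotypes for the validation records (align by column name in
    # case the training solve dropped further dependent columns)
    b = np.array([solution.fixed.get(name, 0.0) for name in kept_names])
    y_c = full_design.y[val_rows] - X_kept[val_rows] @ b

    ids = solution.animal_ids
    dbv_map = dict(zip(ids, solution.dbv))
    sbv_map = dict(zip(ids, solution.sbv)) if solution.sbv is not None else None
    val_pens = phenotypes.loc[is_val, ["animal", "pen"]]
    cbv = combined_breeding_value(dbv_map, sbv_map, val_pens)
    cbv = cbv.loc[phenotypes.animal[is_val]].to_numpy()

    if (np.std(y_c) <= 1e-10 * max(1.0, float(np.abs(y_c).max(initial=0.0)))
            or np.std(cbv) <= 1e-10 * max(1.0, float(np.abs(cbv).max(initial=0.0)))):
        raise ValueError(
            "corrected phenotypes or CBVs have (numerically) zero variance; "
            "correlation undefined"
        )
    corr = float(np.corrcoef(cbv, y_c)[0, 1])
    return corr, pd.DataFrame(
        {"animal": phenotypes.animal[is_val].to_numpy(), "CBV": cbv, "y_c": y_c}
    )
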