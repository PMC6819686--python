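"""Fixed/random design structure for the classic and social animal models.

Model (social variant):

    y = X b + Z_D a_D + Z_S a_S + W l + V g + e

with batch, sex and group-size class fixed effects plus an age-at-target-
weight covariate in X; Z_D the usual record-to-animal incidence; Z_S placing
the dilution factor d_g on every pen mate of the record's animal; W and V
the litter and pen incidences.  The classic variant omits Z_S.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pedigree import PedigreeTable


class ModelSpecError(ValueError):
    pass


@dataclass
class SocialModelSpec:
    """Which terms enter the model and how relationships are propagated.

    relationship is a label ("pedigree" or "single-step"); the actual
    relationship inverse is supplied to the REML engine separately.
    """

    include_social: bool = True
    relationship: str = "pedigree"
    tau: float = 1.0
    omega: float = 1.0
    dilution_enabled: bool = True
    include_litter: bool = True
    include_group: bool = True
    fixed_batch: bool = True
    fixed_sex: bool = True
    fixed_group_size: bool = True
    age_covariate: bool = True
    avg_group_size: float | None = None  # computed from data when None
    keep_singleton_pens: bool = True

    @property
    def n_variance_parameters(self) -> int:
        k = 1 + int(self.include_litter) + int(self.include_group) + 1  # aD + e
        if self.include_social:
            k += 2  # covariance + social variance
        return k


@dataclass
class DesignMatrices:
    """Sparse incidence matrices plus the index maps needed to interpret them."""

    X: sp.csr_matrix
    Z_D: sp.csr_matrix
    Z_S: sp.csr_matrix | None
    W: sp.csr_matrix | None
    V: sp.csr_matrix | None
    y: np.ndarray
    fixed_names: list
    animal_ids: np.ndarray          # pedigree order; columns of Z_D / Z_S
    record_animals: np.ndarray      # animal id per record row
    litter_ids: np.ndarray = field(default_factory=lambda: np.array([]))
    group_ids: np.ndarray = field(default_factory=lambda: np.array([]))
    avg_group_size: float = 1.0
    group_sizes: np.ndarray = field(default_factory=lambda: np.array([]))  # per record
    pen_of_record: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_records(self) -> int:
        return self.X.shape[0]


def dilution_factor(group_size: int, avg_group_size: float, enabled: bool = True) -> float:
    """Dilution covariate d = sqrt((n_bar - 1) / (n_g - 1)).

    Scales social incidences so the heritable social variance is comparable
    across group sizes; d = 0 for a pen of one (no mates), d = 1 with
    dilution disabled.
    """
    if not enabled:
        return 1.0
    if group_size < 1:
        raise ModelSpecError(f"group size must be >= 1, got {group_size}")
    if group_size == 1:
        return 0.0
    if avg_group_size <= 1.0:
        raise ModelSpecError(
            f"average group size must exceed 1 with dilution enabled, got {avg_group_size}"
        )
    return float(np.sqrt((avg_group_size - 1.0) / (group_size - 1.0)))


def group_size_filter(phenotypes: pd.DataFrame, min_frequency: float = 0.10) -> pd.DataFrame:
    """Drop records in pens whose size class holds <= min_frequency of records."""
    ph = phenotypes.copy()
    sizes = ph.groupby("pen")["animal"].transform("size")
    freq = sizes.map(sizes.value_counts(normalize=True))
    keep = freq > min_frequency
    out = ph[keep].reset_index(drop=True)
    if out.empty:
        raise ModelSpecError("group-size filter removed every record")
    return out


def _class_columns(values: pd.Series, prefix: str):
    """Reference-coded (first level dropped) indicator columns for a class effect."""
    levels = sorted(pd.unique(values))
    cols, names = [], []
    for lev in levels[1:]:
        cols.append((values == lev).to_numpy(dtype=float))
        names.append(f"{prefix}[{lev}]")
    return cols, names


def build_design(
    phenotypes: pd.DataFrame,
    pedigree: PedigreeTable,
    spec: SocialModelSpec,
) -> DesignMatrices:
    """Assemble X, Z_D, Z_S, W, V for the given model specification.

    Requires phenotype columns animal, adg, batch, sex, pen, litter, age_days.
    Every pen must sit inside one batch and one sex; every phenotyped animal
    must be in the pedigree.
    """
    ph = phenotypes.reset_index(drop=True)
    n = len(ph)
    if n == 0:
        raise ModelSpecError("no phenotype records")
    for pen, grp in ph.groupby("pen"):
        if grp.batch.nunique() > 1:
            raise ModelSpecError(f"pen {pen} spans multiple batches")
        if grp.sex.nunique() > 1:
            raise ModelSpecError(f"pen {pen} mixes sexes")
    animal_index = pedigree.indices_of(ph.animal)  # raises if missing
    n_animals = len(pedigree)

    pen_sizes = ph.groupby("pen")["animal"].transform("size").to_numpy()
    n_bar = spec.avg_group_size or float(pen_sizes.mean())

    # ---- fixed effects ----
    cols = [np.ones(n)]
    names = ["intercept"]
    if spec.fixed_batch:
        c, nm = _class_columns(ph.batch, "batch")
        cols += c
        names += nm
    if spec.fixed_sex:
        c, nm = _class_columns(ph.sex, "sex")
        cols += c
        names += nm
    if spec.fixed_group_size:
        c, nm = _class_columns(pd.Series(pen_sizes), "group_size")
        cols += c
        names += nm
    if spec.age_covariate and "age_days" in ph:
        cols.append(ph.age_days.to_numpy(dtype=float))
        names.append("age_days")
    X = sp.csr_matrix(np.column_stack(cols))

    rows = np.arange(n)
    Z_D = sp.csr_matrix(
        (np.ones(n), (rows, animal_index)), shape=(n, n_animals)
    )

    Z_S = None
    if spec.include_social:
        ri, ci, vv = [], [], []
        for pen, grp in ph.groupby("pen"):
            idx = grp.index.to_numpy()
            a_ix = animal_index[idx]
            n_g = len(idx)
            d_g = dilution_factor(n_g, n_bar, spec.dilution_enabled)
            for r, a in zip(idx, a_ix):
                for b in a_ix:
                    if b != a:
                        ri.append(r)
                        ci.append(b)
                        vv.append(d_g)
        Z_S = sp.csr_matrix((vv, (ri, ci)), shape=(n, n_animals))

    W = litter_ids = None
    if spec.include_litter:
        litter_ids = np.sort(pd.unique(ph.litter))
        lmap = {l: j for j, l in enumerate(litter_ids)}
        W = sp.csr_matrix(
            (np.ones(n), (rows, ph.litter.map(lmap))), shape=(n, len(litter_ids))
        )
    V = group_ids = None
    if spec.include_group:
        group_ids = np.sort(pd.unique(ph.pen))
        gmap = {g: j for j, g in enumerate(group_ids)}
        V = sp.csr_matrix(
            (np.ones(n), (rows, ph.pen.map(gmap))), shape=(n, len(group_ids))
        )

    return DesignMatrices(
        X=X,
        Z_D=Z_D,
        Z_S=Z_S,
        W=W,
        V=V,
        y=ph.adg.to_numpy(dtype=float),
        fixed_names=names,
        animal_ids=pedigree.ids,
        record_animals=ph.animal.to_numpy(),
        litter_ids=litter_ids if litter_ids is not None else np.array([]),
        group_ids=group_ids if group_ids is not None else np.array([]),
        avg_group_size=n_bar,
        group_sizes=pen_sizes,
        pen_of_record=ph.pen.to_numpy(),
    )
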