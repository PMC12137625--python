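"""TSS-weighted ensemble species distribution models.

Per species: presence cells plus randomly drawn pseudo-absence cells are
split 75/25 into training and evaluation sets, repeated ``n_repeats``
times; several learners are fitted per repeat; each member is scored with
the true skill statistic (TSS = sensitivity + specificity - 1) on its
held-out split at the max-TSS binarisation threshold; members with
TSS >= 0.7 are retained and combined into a weighted-mean suitability
surface with weights proportional to TSS. Cells with ensemble suitability
>= 0.66 form the predicted presence area. Species with fewer than five
records are not modelled: their presence is taken directly from their
recorded cells (the fallback route), as is that of any species for which
no ensemble member clears the TSS bar.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .envstack import EnvStack

__all__ = [
    "SdmConfig",
    "SpeciesEnsemble",
    "MemberModel",
    "sample_pseudo_absences",
    "compute_tss",
    "fit_species_ensemble",
    "fit_all_species",
    "classify_suitability",
    "presence_matrix",
    "predicted_cells",
    "model_report",
    "SUITABILITY_CLASSES",
]

logger = logging.getLogger(__name__)

SUITABILITY_CLASSES = ("unsuitable", "low", "medium", "most")

DEFAULT_LEARNERS = ("logreg", "rf", "gbt")


def make_learner(name: str, random_state: int):
    if name == "logreg":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(max_iter=1000, random_state=random_state)),
        ])
    if name == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=random_state, n_jobs=1)
    if name == "gbt":
        return GradientBoostingClassifier(n_estimators=100, random_state=random_state)
    raise ValueError(f"unknown learner '{name}'")


@dataclass
class SdmConfig:
    """Knobs of the ensemble workflow; defaults follow common practice for
    presence-only ensemble modelling on gridded data."""

    n_pseudo_absence: int = 500
    n_repeats: int = 3
    train_fraction: float = 0.75
    tss_min: float = 0.7
    presence_threshold: float = 0.66
    min_records: int = 5
    learners: tuple[str, ...] = DEFAULT_LEARNERS
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        for name, v in (("tss_min", self.tss_min), ("presence_threshold", self.presence_threshold)):
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_repeats < 1 or self.n_pseudo_absence < 1:
            raise ValueError("n_repeats and n_pseudo_absence must be >= 1")


@dataclass
class MemberModel:
    learner: str
    repeat: int
    tss: float
    threshold: float
    retained: bool
    weight: float = 0.0


@dataclass
class SpeciesEnsemble:
    """Fitted ensemble for one species (or its fallback record-based range)."""

    species_id: str
    members: list[MemberModel]
    ensemble_suitability: np.ndarray | None  # grid in [0,1]; None for fallback
    presence: np.ndarray                     # binary grid
    fallback: bool
    recorded_cells: set[tuple[int, int]]

    def presence_cell_set(self) -> set[tuple[int, int]]:
        rows, cols = np.nonzero(self.presence)
        return set(zip(rows.tolist(), cols.tolist()))


def sample_pseudo_absences(
    presence_cells: set[tuple[int, int]],
    stack: EnvStack,
    n: int,
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Draw ``n`` pseudo-absence cells uniformly (without replacement) from
    valid non-presence cells; if fewer than ``n`` exist, all are used."""
    candidates = [c for c in stack.valid_cells() if c not in presence_cells]
    if not candidates:
        raise ValueError("no candidate cells available for pseudo-absences")
    rng = np.random.default_rng(seed)
    if len(candidates) <= n:
        if len(candidates) < n:
            warnings.warn(
                f"only {len(candidates)} candidate cells for {n} pseudo-absences; using all",
                stacklevel=2,
            )
        return list(candidates)
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in sorted(idx)]


def compute_tss(predicted, observed) -> float:
    """True skill statistic of a binary prediction.

    ``predicted`` may be binary labels, or continuous scores, in which case
    they are binarised at the threshold maximising TSS on these data (the
    standard max-TSS rule). Raises if ``observed`` contains one class only.
    """
    observed = np.asarray(observed)
    predicted = np.asarray(predicted, dtype=float)
    if observed.min() == observed.max():
        raise ValueError("TSS undefined: observed labels are all one class")
    uniq = np.unique(predicted)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        tss, _ = _max_tss(predicted, observed)
        return tss
    return _tss_binary(predicted.astype(int), observed)


def _tss_binary(pred: np.ndarray, obs: np.ndarray) -> float:
    pos = obs == 1
    sens = float(np.mean(pred[pos] == 1))
    spec = float(np.mean(pred[~pos] == 0))
    return sens + spec - 1.0


def _max_tss(scores: np.ndarray, obs: np.ndarray) -> tuple[float, float]:
    """Max-TSS threshold search over the observed score values."""
    thresholds = np.unique(scores)
    best = (-np.inf, 0.5)
    for t in thresholds:
        tss = _tss_binary((scores >= t).astype(int), obs)
        if tss > best[0]:
            best = (tss, float(t))
    return best


def _fallback_presence(recorded: set[tuple[int, int]], stack: EnvStack) -> np.ndarray:
    presence = np.zeros(stack.grid.shape, dtype=np.int8)
    for r, c in recorded:
        presence[r, c] = 1
    return presence


def fit_species_ensemble(
    records: set[tuple[int, int]] | list[tuple[int, int]],
    stack: EnvStack,
    config: SdmConfig,
    species_id: str = "species",
    seed: int | None = None,
) -> SpeciesEnsemble:
    """Fit the TSS-weighted ensemble for one species from its presence cells.

    ``records`` are occupied raster cells (one presence per cell after
    thinning). Species with fewer than ``config.min_records`` cells, or for
    which no member reaches ``config.tss_min``, take the fallback route:
    presence exactly at the recorded cells.
    """
    recorded = {c for c in records}
    if seed is None:
        seed = config.seed
    if len(recorded) < config.min_records:
        return SpeciesEnsemble(species_id, [], None, _fallback_presence(recorded, stack),
                               fallback=True, recorded_cells=recorded)

    presence_list = sorted(recorded)
    members: list[MemberModel] = []
    fitted = []  # (member, model) for retained prediction
    for rep in range(config.n_repeats):
        rep_ss = np.random.SeedSequence([abs(int(seed)) % (2**31), rep + 1])
        pa_seed, split_seed, *learner_seeds = [
            int(s.generate_state(1)[0] % (2**31))
            for s in rep_ss.spawn(2 + len(config.learners))
        ]
        pa_cells = sample_pseudo_absences(recorded, stack, config.n_pseudo_absence, seed=pa_seed)
        cells = presence_list + pa_cells
        X = stack.values_at(cells)
        y = np.concatenate([np.ones(len(presence_list)), np.zeros(len(pa_cells))]).astype(int)
        X_tr, X_ev, y_tr, y_ev = train_test_split(
            X, y, train_size=config.train_fraction, stratify=y, random_state=split_seed)
        if y_ev.min() == y_ev.max():  # degenerate split; cannot score
            warnings.warn(f"{species_id}: evaluation split single-class in repeat {rep}",
                          stacklevel=2)
            continue
        for lname, lseed in zip(config.learners, learner_seeds):
            model = make_learner(lname, random_state=lseed)
            try:
                model.fit(X_tr, y_tr)
                scores = model.predict_proba(X_ev)[:, 1]
            except Exception as exc:  # degenerate training data etc.
                warnings.warn(f"{species_id}: learner {lname} failed in repeat {rep}: {exc}",
                              stacklevel=2)
                continue
            tss, thr = _max_tss(scores, y_ev)
            member = MemberModel(lname, rep, tss=tss, threshold=thr,
                                 retained=bool(tss >= config.tss_min))
            members.append(member)
            if member.retained:
                fitted.append((member, model))

    if not fitted:
        logger.info("%s: no member reached TSS >= %.2f; fallback to recorded cells",
                    species_id, config.tss_min)
        return SpeciesEnsemble(species_id, members, None,
                               _fallback_presence(recorded, stack),
                               fallback=True, recorded_cells=recorded)

    total_tss = sum(m.tss for m, _ in fitted)
    suit = np.full(stack.grid.shape, np.nan)
    valid = stack.valid_cells()
    X_all = stack.values_at(valid)
    acc = np.zeros(len(valid))
    for member, model in fitted:
        member.weight = member.tss / total_tss
        acc += member.weight * model.predict_proba(X_all)[:, 1]
    for (r, c), v in zip(valid, acc):
        suit[r, c] = v
    presence = np.where(np.isnan(suit), 0, (suit >= config.presence_threshold)).astype(np.int8)
    return SpeciesEnsemble(species_id, members, suit, presence,
                           fallback=False, recorded_cells=recorded)


def fit_all_species(
    occupancy: dict[str, set[tuple[int, int]]],
    stack: EnvStack,
    config: SdmConfig,
) -> dict[str, SpeciesEnsemble]:
    """Fit every species, with per-species seeds derived from
    (config.seed, species index in sorted order) so runs are reproducible
    regardless of iteration order."""
    out: dict[str, SpeciesEnsemble] = {}
    for idx, sp in enumerate(sorted(occupancy)):
        sp_seed = int(np.random.SeedSequence([config.seed, idx]).generate_state(1)[0] % (2**31))
        out[sp] = fit_species_ensemble(occupancy[sp], stack, config,
                                       species_id=sp, seed=sp_seed)
    return out


def classify_suitability(suitability: np.ndarray) -> np.ndarray:
    """Four-level habitat suitability classification.

    Bins (half-open, last closed): [0, 0.05) unsuitable, [0.05, 0.33) low,
    [0.33, 0.66) medium, [0.66, 1] most suitable. NaN stays NaN (coded -1).
    """
    arr = np.asarray(suitability, dtype=float)
    finite = np.isfinite(arr)
    if np.any((arr[finite] < 0) | (arr[finite] > 1)):
        raise ValueError("suitability values must lie in [0, 1]")
    classes = np.digitize(arr, [0.05, 0.33, 0.66], right=False)
    classes = np.where(finite, classes, -1)
    return classes.astype(int)


def predicted_cells(ensembles: dict[str, SpeciesEnsemble]) -> dict[str, set[tuple[int, int]]]:
    """Species -> set of predicted-presence cells (fallback species included
    via their recorded cells)."""
    return {sp: ens.presence_cell_set() for sp, ens in ensembles.items()}


def presence_matrix(ensembles: dict[str, SpeciesEnsemble], config: SdmConfig) -> pd.DataFrame:
    """Species x flat-cell binary presence matrix.

    Modelled species: presence where ensemble suitability >= the presence
    threshold; fallback species: presence exactly at their recorded cells.
    """
    if not ensembles:
        return pd.DataFrame()
    first = next(iter(ensembles.values()))
    n_rows, n_cols = first.presence.shape
    data = {sp: ens.presence.ravel() for sp, ens in sorted(ensembles.items())}
    return pd.DataFrame.from_dict(data, orient="index",
                                  columns=range(n_rows * n_cols)).astype(np.int8)


def model_report(ensembles: dict[str, SpeciesEnsemble]) -> pd.DataFrame:
    """Per-member fit report: species, learner, repeat, TSS, retained, weight, fallback."""
    rows = []
    for sp, ens in sorted(ensembles.items()):
        if not ens.members:
            rows.append((sp, "", -1, np.nan, False, np.nan, ens.fallback))
        for m in ens.members:
            rows.append((sp, m.learner, m.repeat, m.tss, m.retained, m.weight, ens.fallback))
    return pd.DataFrame(rows, columns=[
        "species", "learner", "repeat", "tss", "retained", "weight", "fallback"])
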