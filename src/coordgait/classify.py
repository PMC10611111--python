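"""Participant-grouped classification protocol.

The feature table holds 10 'combined movement' rows per participant.  Each
protocol iteration runs leave-one-participant-out cross-validation: for
every fold the held-out participant's 10 rows form the test set, adaptive
synthetic oversampling (ADASYN) rebalances the remaining training rows, a
300-tree Gini random forest is fitted, the 10 row predictions are reduced
to one participant label by majority vote (ties broken uniformly at
random), and mean-decrease-impurity feature importances are recorded.
Probabilities per participant are prediction frequencies over iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors

from .features import ALL_FEATURES, build_feature_row

log = logging.getLogger(__name__)

LABELS = ("EOA", "DCD", "CTRL")


@dataclass(frozen=True)
class ClassifierConfig:
    n_trees: int = 300
    split_criterion: str = "gini"
    features_per_split: str = "sqrt"
    bootstrap: bool = True
    adasyn_neighbors: int = 5
    n_iterations: int = 100
    rows_per_participant: int = 10
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.n_iterations < 1:
            raise ValueError("n_trees and n_iterations must be >= 1")


@dataclass
class AssembledTable:
    """10 rows per participant; features in catalog order."""

    df: pd.DataFrame
    feature_names: tuple[str, ...] = ALL_FEATURES
    replacement_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ("participant_id", "group", *self.feature_names)
                   if c not in self.df.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        X = self.df[list(self.feature_names)].to_numpy(dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("feature table contains non-finite values")

    @property
    def participants(self) -> list[str]:
        return list(dict.fromkeys(self.df["participant_id"]))

    @property
    def groups(self) -> dict[str, str]:
        return dict(zip(self.df["participant_id"], self.df["group"]))

    def matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(X, y, pid) arrays in row order."""
        return (self.df[list(self.feature_names)].to_numpy(dtype=float),
                self.df["group"].to_numpy(),
                self.df["participant_id"].to_numpy())


@dataclass
class RunResult:
    labels: tuple[str, ...]
    participants: list[str]
    groups: dict[str, str]
    predictions: pd.DataFrame            # columns: iteration, participant_id, predicted
    probabilities: pd.DataFrame          # participant x labels
    confusion_mean_pct: np.ndarray       # (k, k) row %
    confusion_sd_pct: np.ndarray
    importance_mean: pd.Series           # per feature, sums to 1
    importance_sd: pd.Series
    iteration_seeds: list[int]
    config: ClassifierConfig


def assemble_table(features_by_participant: dict[str, tuple[pd.DataFrame, pd.DataFrame, str]],
                   rng_seed: int = 0,
                   rows_per_participant: int = 10) -> AssembledTable:
    """Pair randomly chosen gait and tandem cycles into 'combined movement'
    rows, 10 per participant.

    ``features_by_participant`` maps participant id to
    (gait per-cycle table, tandem per-cycle table, group label).  Cycles are
    drawn without replacement when enough are available, with replacement
    otherwise (flagged).  Participants lacking usable cycles in either test
    are excluded with a logged reason.
    """
    rng = np.random.default_rng(rng_seed)
    rows, flags = [], {}
    for pid in sorted(features_by_participant):
        gait_df, tandem_df, group = features_by_participant[pid]
        if gait_df is None or tandem_df is None or not len(gait_df) or not len(tandem_df):
            log.warning("participant %s excluded: no usable cycles in one test", pid)
            continue

        def pick(df: pd.DataFrame) -> tuple[np.ndarray, bool]:
            n = len(df)
            if n >= rows_per_participant:
                return rng.choice(n, rows_per_participant, replace=False), False
            return rng.choice(n, rows_per_participant, replace=True), True

        gi, g_rep = pick(gait_df)
        ti, t_rep = pick(tandem_df)
        flags[pid] = g_rep or t_rep
        for a, b in zip(gi, ti):
            rows.append(build_feature_row(gait_df.iloc[a], tandem_df.iloc[b],
                                          pid, pid, pid, group))
    if not rows:
        raise ValueError("no participants with usable cycles")
    return AssembledTable(pd.DataFrame(rows), replacement_flags=flags)


def adasyn_oversample(X: np.ndarray, y: np.ndarray, k: int = 5,
                      rng: np.random.Generator | None = None
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Adaptive synthetic oversampling of every minority class up to the
    majority count.

    Per minority sample, the share of generated offspring is proportional to
    the fraction of out-of-class neighbors among its k nearest neighbors in
    the full training set (harder samples get more offspring); each synthetic
    point lies on the segment between the sample and one of its same-class
    neighbors.  When a minority class sits in a region with no out-of-class
    neighbors at all, offspring are allocated uniformly so the balance
    contract still holds.

    Returns (X_aug, y_aug, synthetic_mask).
    """
    rng = rng or np.random.default_rng()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("ADASYN requires at least two classes")
    n_major = int(counts.max())

    X_out, y_out = [X], [y]
    n_synth_total = 0
    for cls, n_c in zip(classes, counts):
        G = n_major - int(n_c)
        if G <= 0:
            continue
        idx_c = np.flatnonzero(y == cls)
        Xc = X[idx_c]
        if len(idx_c) >= 2:
            k_density = min(k, X.shape[0] - 1)
            nn_all = NearestNeighbors(n_neighbors=k_density + 1).fit(X)
            _, nbrs = nn_all.kneighbors(Xc)
            nbrs = nbrs[:, 1:]  # drop self
            r = (y[nbrs] != cls).mean(axis=1)
            if r.sum() == 0.0:
                r = np.ones(len(idx_c))
            r = r / r.sum()
            # largest-remainder allocation keeps the total exactly G
            raw = r * G
            g = np.floor(raw).astype(int)
            rem = G - g.sum()
            if rem > 0:
                order = np.argsort(-(raw - g))
                g[order[:rem]] += 1

            k_gen = min(k, len(idx_c) - 1)
            nn_c = NearestNeighbors(n_neighbors=k_gen + 1).fit(Xc)
            _, nbrs_c = nn_c.kneighbors(Xc)
            nbrs_c = nbrs_c[:, 1:]
            synth = []
            for i, gi in enumerate(g):
                for _ in range(gi):
                    z = Xc[rng.choice(nbrs_c[i])]
                    lam = rng.uniform()
                    synth.append(Xc[i] + lam * (z - Xc[i]))
        else:
            synth = [Xc[0]] * G  # single exemplar: duplicate
        if synth:
            X_out.append(np.asarray(synth))
            y_out.append(np.full(len(synth), cls, dtype=y.dtype))
            n_synth_total += len(synth)

    X_aug = np.vstack(X_out)
    y_aug = np.concatenate(y_out)
    synthetic = np.zeros(X_aug.shape[0], dtype=bool)
    synthetic[X.shape[0]:] = True
    return X_aug, y_aug, synthetic


def majority_vote(row_preds: np.ndarray, rng: np.random.Generator) -> str:
    """Most frequent row label; ties resolved uniformly at random."""
    labels, counts = np.unique(row_preds, return_counts=True)
    winners = labels[counts == counts.max()]
    if winners.size == 1:
        return str(winners[0])
    return str(rng.choice(winners))


def loocv_iteration(table: AssembledTable, cfg: ClassifierConfig,
                    iteration_seed: int,
                    fold_log: list[dict] | None = None
                    ) -> tuple[dict[str, str], np.ndarray]:
    """One leave-one-participant-out pass.

    Returns (participant -> predicted label, per-fold importance matrix).
    When ``fold_log`` is a list, one diagnostic record per fold is appended
    (held-out id, training participant ids, post-ADASYN class counts).
    """
    X, y, pid = table.matrices()
    participants = table.participants
    if len(participants) < 3 or np.unique(y).size < len(LABELS):
        raise ValueError("need >= 3 participants spanning all classes")
    rng = np.random.default_rng(iteration_seed)
    preds: dict[str, str] = {}
    importances = np.empty((len(participants), len(table.feature_names)))

    for f, held in enumerate(participants):
        test_mask = pid == held
        train_mask = ~test_mask
        X_test = X[test_mask]
        if not np.isfinite(X_test).all():
            raise ValueError(f"held-out rows for {held} contain non-finite values")
        # leakage guard: the held-out participant must be absent from training
        assert held not in set(pid[train_mask]), "participant leakage detected"
        X_tr, y_tr, synth = adasyn_oversample(X[train_mask], y[train_mask],
                                              k=cfg.adasyn_neighbors, rng=rng)
        if fold_log is not None:
            labs, cnts = np.unique(y_tr, return_counts=True)
            fold_log.append({
                "held_out": held,
                "train_participants": set(pid[train_mask]),
                "n_synthetic": int(synth.sum()),
                "class_counts_after": dict(zip(map(str, labs), map(int, cnts))),
            })
        clf = RandomForestClassifier(
            n_estimators=cfg.n_trees, criterion=cfg.split_criterion,
            max_features=cfg.features_per_split, bootstrap=cfg.bootstrap,
            random_state=int(rng.integers(2 ** 31 - 1)), n_jobs=1)
        clf.fit(X_tr, y_tr)
        preds[held] = majority_vote(clf.predict(X_test), rng)
        importances[f] = clf.feature_importances_
    return preds, importances


def confusion_percent(preds: dict[str, str], groups: dict[str, str],
                      labels: tuple[str, ...] = LABELS) -> np.ndarray:
    """Row-percentage confusion matrix of one iteration's predictions."""
    k = len(labels)
    counts = np.zeros((k, k))
    for p, pred in preds.items():
        counts[labels.index(groups[p]), labels.index(pred)] += 1
    sizes = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sizes > 0, counts / sizes * 100.0, 0.0)


def run_protocol(table: AssembledTable, cfg: ClassifierConfig,
                 fold_log: list[dict] | None = None) -> RunResult:
    """n_iterations independent LOOCV passes with a seed ladder derived from
    the master seed."""
    participants = table.participants
    groups = table.groups
    ss = np.random.SeedSequence(cfg.master_seed)
    seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(cfg.n_iterations)]

    pred_rows = []
    conf = np.empty((cfg.n_iterations, len(LABELS), len(LABELS)))
    imp = np.empty((cfg.n_iterations, len(table.feature_names)))
    for it, seed in enumerate(seeds):
        preds, fold_imp = loocv_iteration(table, cfg, seed, fold_log=fold_log)
        for p, lab in preds.items():
            pred_rows.append({"iteration": it, "participant_id": p,
                              "predicted": lab})
        conf[it] = confusion_percent(preds, groups)
        imp[it] = fold_imp.mean(axis=0)
        imp[it] /= imp[it].sum()

    predictions = pd.DataFrame(pred_rows)
    prob = (predictions.pivot_table(index="participant_id", columns="predicted",
                                    aggfunc="size", fill_value=0)
            .reindex(index=participants, columns=list(LABELS), fill_value=0)
            / cfg.n_iterations)
    prob.columns.name = None
    return RunResult(
        labels=LABELS,
        participants=participants,
        groups=groups,
        predictions=predictions,
        probabilities=prob,
        confusion_mean_pct=conf.mean(axis=0),
        confusion_sd_pct=conf.std(axis=0, ddof=0),
        importance_mean=pd.Series(imp.mean(axis=0), index=table.feature_names),
        importance_sd=pd.Series(imp.std(axis=0, ddof=0), index=table.feature_names),
        iteration_seeds=seeds,
        config=cfg,
    )


def participant_accuracy(result: RunResult) -> float:
    """Fraction of (iteration, participant) predictions that are correct."""
    correct = [row.predicted == result.groups[row.participant_id]
               for row in result.predictions.itertuples()]
    return float(np.mean(correct))
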