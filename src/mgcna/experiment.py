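"""Evaluation protocols: negative sampling, splits, cross-validation,
metrics and case-study ranking.

The central leakage rule: the two MDA-based views are functions of the
*training* positives of the current fold only, so they are rebuilt inside
every fold before the model sees them.  The feature-based views
(sequence, structure, gene profiles) do not depend on the labels and are
shared across folds.

Negatives are sampled once per experiment, balanced 1:1 with the
positives, then partitioned into folds together with the positives.  In
cold-start modes, pairs are assigned to folds by their entity's fold, so
the train/test entity-disjointness constraint holds for negatives too.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from ._random import substream
from .dataset import Dataset
from .io import BipartiteAssociations, PredictionRecord
from .model import MGCNAModel, ModelConfig
from .views import ViewBundle, build_view_bundle

logger = logging.getLogger(__name__)

SPLIT_MODES = ("random_pair", "mirna_cold", "drug_cold", "pair_cold")

#: Labelled pair: (mirna_id, drug_id, label)
Pair = tuple[str, str, int]


@dataclass
class SplitPlan:
    """Per-fold train/test pair lists under one split protocol."""

    mode: str
    n_folds: int
    seed: int
    folds: list[dict[str, list[Pair]]] = field(default_factory=list)


@dataclass
class MetricReport:
    """Per-fold and mean ranking metrics of a cross-validation run."""

    mode: str
    fold_auc: list[float]
    fold_aupr: list[float]
    fold_predictions: list[list[PredictionRecord]] = field(default_factory=list)

    @property
    def auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def aupr(self) -> float:
        return float(np.mean(self.fold_aupr))

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "auc": self.auc,
            "aupr": self.aupr,
            "fold_auc": self.fold_auc,
            "fold_aupr": self.fold_aupr,
        }


def sample_negatives(
    positives: BipartiteAssociations,
    rng: np.random.Generator,
    n: int | None = None,
) -> list[tuple[str, str]]:
    """Uniform sample, without replacement, of unknown miRNA-drug pairs.

    Defaults to a balanced sample (one negative per positive).
    """
    n_m, n_d = positives.shape
    n_pos = len(positives.pairs)
    if n is None:
        n = n_pos
    n_unknown = n_m * n_d - n_pos
    if n > n_unknown:
        raise ValueError(f"requested {n} negatives but only {n_unknown} unknown pairs")
    mat = positives.matrix()
    unknown = np.flatnonzero(mat.ravel() == 0)
    chosen = rng.choice(unknown, size=n, replace=False)
    rows, cols = np.unravel_index(chosen, mat.shape)
    return [(positives.row_ids[i], positives.col_ids[j])
            for i, j in zip(rows, cols)]


def _partition(items: list, n_folds: int, rng: np.random.Generator) -> list[list]:
    items = list(items)
    order = rng.permutation(len(items))
    folds: list[list] = [[] for _ in range(n_folds)]
    for rank, idx in enumerate(order):
        folds[rank % n_folds].append(items[idx])
    return folds


def make_splits(
    pairs: Sequence[Pair],
    mode: str = "random_pair",
    n_folds: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """Assign labelled pairs to cross-validation folds.

    ``random_pair``: stratified random partition of the pairs.
    ``mirna_cold`` / ``drug_cold``: the entities of one side are
    partitioned into folds and each pair follows its entity, so no test
    entity of that side ever appears in a training pair.
    ``pair_cold``: both sides are partitioned independently; fold f tests
    the pairs whose miRNA and drug are both held out, trains on pairs with
    neither held out, and drops pairs with exactly one held-out entity.
    """
    if mode not in SPLIT_MODES:
        raise ValueError(f"unknown split mode {mode!r}; expected one of {SPLIT_MODES}")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    pairs = sorted(pairs)  # determinism regardless of input order
    rng = substream(seed, f"splits/{mode}")
    plan = SplitPlan(mode=mode, n_folds=n_folds, seed=seed)

    if mode == "random_pair":
        pos = [p for p in pairs if p[2] == 1]
        neg = [p for p in pairs if p[2] == 0]
        fold_sets = [a + b for a, b in
                     zip(_partition(pos, n_folds, rng), _partition(neg, n_folds, rng))]
        for f in range(n_folds):
            test = fold_sets[f]
            train = [p for g, fs in enumerate(fold_sets) if g != f for p in fs]
            plan.folds.append({"train": train, "test": test})
        return plan

    mirnas = sorted({m for m, _, _ in pairs})
    drugs = sorted({d for _, d, _ in pairs})
    if mode in ("mirna_cold", "pair_cold") and len(mirnas) < n_folds:
        raise ValueError(f"only {len(mirnas)} miRNAs for {n_folds} folds")
    if mode in ("drug_cold", "pair_cold") and len(drugs) < n_folds:
        raise ValueError(f"only {len(drugs)} drugs for {n_folds} folds")

    if mode in ("mirna_cold", "drug_cold"):
        side = 0 if mode == "mirna_cold" else 1
        ents = mirnas if side == 0 else drugs
        fold_of = {e: f for f, grp in enumerate(_partition(ents, n_folds, rng))
                   for e in grp}
        for f in range(n_folds):
            test = [p for p in pairs if fold_of[p[side]] == f]
            train = [p for p in pairs if fold_of[p[side]] != f]
            plan.folds.append({"train": train, "test": test})
        return plan

    m_fold = {e: f for f, grp in enumerate(_partition(mirnas, n_folds, rng))
              for e in grp}
    d_fold = {e: f for f, grp in enumerate(_partition(drugs, n_folds, rng))
              for e in grp}
    for f in range(n_folds):
        test = [p for p in pairs if m_fold[p[0]] == f and d_fold[p[1]] == f]
        train = [p for p in pairs if m_fold[p[0]] != f and d_fold[p[1]] != f]
        plan.folds.append({"train": train, "test": test})
    return plan


def compute_auc_aupr(scores: Sequence[float],
                     labels: Sequence[int]) -> tuple[float, float]:
    """AUC (midrank convention for ties) and AUPR (stepwise summation)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present to compute AUC/AUPR")
    return (float(roc_auc_score(labels, scores)),
            float(average_precision_score(labels, scores)))


def _view_checksum(bundle: ViewBundle) -> str:
    h = hashlib.sha256()
    for name in sorted(bundle.mirna_views) + sorted(bundle.drug_views):
        views = bundle.mirna_views if name in bundle.mirna_views else bundle.drug_views
        h.update(name.encode())
        h.update(np.ascontiguousarray(views[name].matrix).tobytes())
    return h.hexdigest()


def _train_and_score(
    dataset: Dataset,
    train_pairs: list[Pair],
    score_pairs: list[tuple[str, str]],
    model_config: ModelConfig,
    seed: int,
    fold_tag: str,
    thresholds=None,
    include=None,
    epochs: int | None = None,
) -> tuple[np.ndarray, ViewBundle, MGCNAModel]:
    """Rebuild MDA views from training positives, train, score pairs."""
    train_pos = {(m, d) for m, d, y in train_pairs if y == 1}
    train_mda = dataset.mda.subset_pairs(train_pos)
    bundle = build_view_bundle(
        dataset.sequences, dataset.fingerprints, dataset.mga, dataset.dga,
        train_mda, thresholds=thresholds, include=include)
    m_idx = {m: i for i, m in enumerate(bundle.mirna_ids)}
    d_idx = {d: j for j, d in enumerate(bundle.drug_ids)}
    x_train = np.array([(m_idx[m], d_idx[d]) for m, d, _ in train_pairs])
    y_train = np.array([y for _, _, y in train_pairs], dtype=np.float64)

    model = MGCNAModel(
        list(bundle.mirna_views.values()), list(bundle.drug_views.values()),
        model_config, substream(seed, f"init/{fold_tag}"))
    model.fit(x_train, y_train, substream(seed, f"dropout/{fold_tag}"),
              epochs=epochs)
    x_score = np.array([(m_idx[m], d_idx[d]) for m, d in score_pairs])
    return model.predict(x_score), bundle, model


def run_cv(
    dataset: Dataset,
    mode: str = "random_pair",
    n_folds: int = 5,
    seed: int = 0,
    model_config: ModelConfig | None = None,
    thresholds=None,
    include=None,
    epochs: int | None = None,
    keep_predictions: bool = False,
) -> MetricReport:
    """Balanced cross-validation of the full pipeline under one protocol.

    Per fold the MDA-based views are rebuilt from that fold's training
    positives and a fresh model is trained; metrics are computed on the
    held-out pairs and averaged over folds.
    """
    cfg = model_config if model_config is not None else ModelConfig()
    positives = sorted(dataset.mda.pairs)
    negatives = sample_negatives(dataset.mda, substream(seed, "negatives"))
    labelled: list[Pair] = [(m, d, 1) for m, d in positives] + \
                           [(m, d, 0) for m, d in negatives]
    plan = make_splits(labelled, mode=mode, n_folds=n_folds, seed=seed)

    report = MetricReport(mode=mode, fold_auc=[], fold_aupr=[])
    for f, fold in enumerate(plan.folds):
        test = fold["test"]
        scores, _, _ = _train_and_score(
            dataset, fold["train"], [(m, d) for m, d, _ in test],
            cfg, seed, f"fold{f}", thresholds, include, epochs)
        y_test = [y for _, _, y in test]
        auc, aupr = compute_auc_aupr(scores, y_test)
        report.fold_auc.append(auc)
        report.fold_aupr.append(aupr)
        if keep_predictions:
            report.fold_predictions.append([
                PredictionRecord(m, d, float(np.clip(s, 0, 1)), y)
                for (m, d, y), s in zip(test, scores)])
        logger.info("%s fold %d: AUC %.4f  AUPR %.4f", mode, f, auc, aupr)
    return report


#: View-combination candidates compared during model selection, mirroring
#: the ablation table of view subsets: every row pairs at least one miRNA
#: view with at least one drug view.
VIEW_SUBSET_CANDIDATES: dict[str, list[str]] = {
    "all_six": ["mirna_seq", "mirna_gene", "mirna_mda",
                "drug_struct", "drug_gene", "drug_mda"],
    "seq_struct": ["mirna_seq", "drug_struct"],
    "gene_profiles": ["mirna_gene", "drug_gene"],
    "mda_only": ["mirna_mda", "drug_mda"],
    "feature_views": ["mirna_seq", "mirna_gene", "drug_struct", "drug_gene"],
    "seq_mda_struct_gene_mda": ["mirna_seq", "mirna_mda",
                                "drug_struct", "drug_gene", "drug_mda"],
}


def compare_view_subsets(
    dataset: Dataset,
    subsets: dict[str, list[str]] | None = None,
    seed: int = 0,
    model_config: ModelConfig | None = None,
    epochs: int | None = None,
    n_folds: int = 5,
    thresholds=None,
) -> dict[str, MetricReport]:
    """Cross-validate each candidate view combination (model selection).

    This is the selection protocol the full method prescribes: the view
    combination actually deployed is the one with the best mean CV AUC,
    not necessarily the union of all available views.
    """
    subsets = subsets if subsets is not None else VIEW_SUBSET_CANDIDATES
    out: dict[str, MetricReport] = {}
    for tag, include in subsets.items():
        out[tag] = run_cv(dataset, n_folds=n_folds, seed=seed,
                          model_config=model_config, thresholds=thresholds,
                          include=include, epochs=epochs)
        logger.info("subset %s: mean AUC %.4f", tag, out[tag].auc)
    return out


def select_view_subset(
    dataset: Dataset,
    subsets: dict[str, list[str]] | None = None,
    seed: int = 0,
    model_config: ModelConfig | None = None,
    epochs: int | None = None,
    n_folds: int = 5,
) -> tuple[str, list[str], dict[str, MetricReport]]:
    """Pick the view combination with the best mean CV AUC (ties: first)."""
    subsets = subsets if subsets is not None else VIEW_SUBSET_CANDIDATES
    reports = compare_view_subsets(dataset, subsets, seed=seed,
                                   model_config=model_config, epochs=epochs,
                                   n_folds=n_folds)
    best = max(reports, key=lambda t: reports[t].auc)
    return best, list(subsets[best]), reports


def run_benchmark(
    dataset: Dataset,
    seed: int = 0,
    model_config: ModelConfig | None = None,
    selection_epochs: int = 150,
    n_folds: int = 5,
) -> dict:
    """Full evaluation pipeline: view-subset selection, then final CV.

    Selection uses shortened training (``selection_epochs``) to rank the
    candidates; the winning combination is then cross-validated at the
    configured epoch count.  Returns the selected subset, the per-subset
    selection metrics and the final report.
    """
    best, include, selection = select_view_subset(
        dataset, seed=seed, model_config=model_config,
        epochs=selection_epochs, n_folds=n_folds)
    final = run_cv(dataset, n_folds=n_folds, seed=seed,
                   model_config=model_config, include=include)
    return {
        "selected_subset": best,
        "selected_views": include,
        "selection": {t: r.to_dict() for t, r in selection.items()},
        "final": final,
    }


def rank_candidates_for_drug(
    dataset: Dataset,
    drug_id: str,
    k: int = 15,
    seed: int = 0,
    model_config: ModelConfig | None = None,
    thresholds=None,
    include=None,
    epochs: int | None = None,
) -> list[PredictionRecord]:
    """Case-study protocol: mask a drug's known associations and rank all
    candidate miRNAs for it.

    The target drug's positives are removed from the association set (so
    the rebuilt MDA views carry no information about it), the model is
    trained on the remaining positives plus an equal number of sampled
    negatives (sampled away from the target drug to keep the candidate
    pool untouched), and every miRNA is scored against the drug.  Returns
    the top-k predictions, descending score, ties broken by miRNA id.
    """
    if drug_id not in dataset.mda.col_ids:
        raise ValueError(f"unknown drug id {drug_id!r}")
    masked = {(m, d) for m, d in dataset.mda.pairs if d == drug_id}
    if not masked:
        raise ValueError(f"drug {drug_id!r} has no known associations to mask")
    remaining = sorted(dataset.mda.pairs - masked)

    pool = BipartiteAssociations(
        dataset.mirna_ids, dataset.drug_ids,
        set(dataset.mda.pairs) | {(m, drug_id) for m in dataset.mirna_ids})
    negatives = sample_negatives(pool, substream(seed, "case/negatives"),
                                 n=len(remaining))
    train_pairs: list[Pair] = [(m, d, 1) for m, d in remaining] + \
                              [(m, d, 0) for m, d in negatives]
    candidates = [(m, drug_id) for m in dataset.mirna_ids]
    cfg = model_config if model_config is not None else ModelConfig()
    scores, bundle, _ = _train_and_score(
        dataset, train_pairs, candidates, cfg, seed, f"case/{drug_id}",
        thresholds, include, epochs)

    records = [PredictionRecord(m, drug_id, float(np.clip(s, 0.0, 1.0)),
                                int((m, drug_id) in dataset.mda.pairs))
               for (m, _), s in zip(candidates, scores)]
    records.sort(key=lambda r: (-r.score, r.mirna_id))
    return records[:k]
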