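"""End-to-end grading pipeline.

The procedure mirrors how the grading model is built in practice:

1. screen continuous features (two-group Kruskal–Wallis, drop p > alpha);
2. learn the network in two parts, because so few patients carry both
   advanced modalities: one part over {grade, enhancement, retained
   perfusion features} on perfusion-complete rows, the other over {grade,
   retained MRSI features} on MRSI-complete rows, each with K2;
3. merge the parts on the shared grade node;
4. evaluate by leave-one-out cross-validation: the structure is held fixed,
   parameters are refitted on the 55 remaining cases per fold, and each held
   -out case is predicted from the evidence allowed by an observation
   pattern (which modalities are read);
5. report accuracy, wrong-prediction counts, ROC points and trapezoidal AUC
   per pattern. A pattern's denominator contains only the cases that carry
   all of its modalities, so perfusion patterns are scored on the
   perfusion-complete subset and MRSI patterns on the MRSI-complete subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import (
    GRADE_COL,
    MODALITY_GROUPS,
    T1WC_COL,
    modality_of,
)
from .network import (
    FittedNetwork,
    NetworkStructure,
    fit_mle,
    predict,
)
from .screening import ScreeningResult, screen_features
from .structure import K2Config, k2_search, node_specs_for

__all__ = [
    "ObservationPattern",
    "EvaluationReport",
    "TwoPartNetwork",
    "build_two_part_network",
    "merge_structures",
    "loocv_evaluate",
    "loocv_evaluate_patterns",
    "feature_subset_sweep",
    "roc_auc",
]

MODALITIES = ("T1WC", "perfusion", "MRSI")


@dataclass(frozen=True)
class ObservationPattern:
    """Which modalities are read as evidence for a prediction.

    ``required`` modalities define the denominator: only cases carrying all
    of them are evaluated. The remaining ``modalities`` are optional — their
    features enter the evidence when present but a case is not dropped for
    lacking them. This distinction reproduces the usual reporting layout:
    e.g. "all 56 cases, enhancement plus whatever perfusion/MRSI each case
    has" is ``T1WC`` required with ``perfusion`` and ``MRSI`` optional.
    In the string form optional modalities carry a trailing ``?``:
    ``"T1WC+perfusion?+MRSI?"``.
    """

    modalities: frozenset
    required: frozenset | None = None

    def __post_init__(self) -> None:
        if not self.modalities:
            raise ValueError("observation pattern must be nonempty")
        unknown = set(self.modalities) - set(MODALITIES)
        if unknown:
            raise ValueError(f"unknown modalities: {sorted(unknown)}")
        if self.required is None:
            object.__setattr__(self, "required", self.modalities)
        if not self.required <= self.modalities:
            raise ValueError("required modalities must be a subset of the "
                             "pattern's modalities")

    @classmethod
    def parse(cls, text: str) -> "ObservationPattern":
        parts = [p for p in text.replace(",", "+").split("+") if p]
        mods, req = set(), set()
        for p in parts:
            if p.endswith("?"):
                mods.add(p[:-1])
            else:
                mods.add(p)
                req.add(p)
        return cls(frozenset(mods), frozenset(req))

    def label(self) -> str:
        out = []
        for m in MODALITIES:
            if m in self.required:
                out.append(m)
            elif m in self.modalities:
                out.append(m + "?")
        return "+".join(out)

    def features_in(self, structure: NetworkStructure) -> list[str]:
        out = []
        for m in MODALITIES:
            if m not in self.modalities:
                continue
            out.extend(f for f in MODALITY_GROUPS[m]
                       if f in structure.nodes)
        return out

    def case_mask(self, table: pd.DataFrame) -> np.ndarray:
        """Rows carrying every required modality."""
        mask = np.ones(len(table), dtype=bool)
        for m in self.required:
            members = [f for f in MODALITY_GROUPS[m] if f in table.columns]
            if members:
                mask &= table[members].notna().all(axis=1).to_numpy()
        return mask


@dataclass
class EvaluationReport:
    pattern: str
    cases: pd.DataFrame  # patient_id, true, predicted, p_high
    accuracy: float
    n_wrong: int
    n_cases: int
    roc_points: np.ndarray
    auc: float
    n_failed_folds: int = 0

    def to_row(self) -> dict:
        return {
            "pattern": self.pattern,
            "n_cases": self.n_cases,
            "accuracy": self.accuracy,
            "n_wrong": self.n_wrong,
            "auc": self.auc,
            "n_failed_folds": self.n_failed_folds,
        }


@dataclass
class TwoPartNetwork:
    merged: NetworkStructure
    part_a: NetworkStructure
    part_b: NetworkStructure
    screening: list[ScreeningResult]
    order_a: tuple[str, ...]
    order_b: tuple[str, ...]
    n_rows_a: int
    n_rows_b: int


def _retained_by_modality(screening: list[ScreeningResult]) -> dict:
    """Retained features per modality, ordered by ascending p-value
    (most significant first) with the name as a deterministic tie-break."""
    out = {"perfusion": [], "MRSI": []}
    kept = [r for r in screening if r.retained]
    for r in sorted(kept, key=lambda r: (r.p_value, r.feature_name)):
        out[modality_of(r.feature_name)].append(r.feature_name)
    return out


def build_two_part_network(
    table: pd.DataFrame,
    alpha: float = 0.05,
    max_parents: int = 3,
    min_rows: int = 10,
    perfusion_features=None,
    mrsi_features=None,
) -> TwoPartNetwork:
    """Screen, learn both parts with K2, and merge on the grade node.

    ``perfusion_features`` / ``mrsi_features`` override the screened lists
    (used by the subset sweep). Each part must have at least ``min_rows``
    complete rows. Grade leads both orderings (followed by the enhancement
    category in the perfusion part), so the merge cannot create a cycle.
    """
    screening = screen_features(table, alpha=alpha)
    retained = _retained_by_modality(screening)
    perf = list(perfusion_features if perfusion_features is not None
                else retained["perfusion"])
    mrsi = list(mrsi_features if mrsi_features is not None
                else retained["MRSI"])

    order_a = (GRADE_COL, T1WC_COL, *perf)
    order_b = (GRADE_COL, *mrsi)

    rows_a = table.dropna(subset=list(order_a))
    rows_b = table.dropna(subset=list(order_b))
    for label, rows in (("T1WC+perfusion part", rows_a), ("MRSI part", rows_b)):
        if len(rows) < min_rows:
            raise ValueError(
                f"{label}: only {len(rows)} complete rows "
                f"(minimum {min_rows})"
            )

    part_a = k2_search(rows_a, K2Config(order_a, max_parents=max_parents))
    part_b = k2_search(rows_b, K2Config(order_b, max_parents=max_parents))
    merged = merge_structures(part_a, part_b)
    return TwoPartNetwork(
        merged, part_a, part_b, screening, order_a, order_b,
        len(rows_a), len(rows_b),
    )


def merge_structures(
    a: NetworkStructure, b: NetworkStructure
) -> NetworkStructure:
    """Union of nodes and edges; shared nodes must agree in type. The
    result is re-validated, so a merge that would introduce a cycle or an
    inadmissible edge is rejected."""
    nodes = dict(a.nodes)
    for name, spec in b.nodes.items():
        if name in nodes and nodes[name] != spec:
            raise ValueError(f"node {name!r} typed differently in the parts")
        nodes[name] = spec
    edges = sorted(set(a.edges) | set(b.edges))
    return NetworkStructure(list(nodes.values()), edges)


# ---------------------------------------------------------------------------
# leave-one-out evaluation

def _fold_networks(table: pd.DataFrame, structure: NetworkStructure,
                   smoothing: float):
    """Lazily fit one network per fold (all rows but one)."""
    cache: dict[int, FittedNetwork | None] = {}

    def get(i: int):
        if i not in cache:
            train = table.drop(index=table.index[i])
            try:
                cache[i] = fit_mle(structure, train, smoothing=smoothing)
            except ValueError:
                cache[i] = None
        return cache[i]

    return get


def loocv_evaluate_patterns(
    table: pd.DataFrame,
    structure: NetworkStructure,
    patterns,
    smoothing: float = 0.0,
) -> dict[str, EvaluationReport]:
    """LOOCV under several observation patterns, sharing the per-fold fits
    (parameters do not depend on the evidence pattern)."""
    get_fold = _fold_networks(table, structure, smoothing)
    reports = {}
    for pattern in patterns:
        if isinstance(pattern, str):
            pattern = ObservationPattern.parse(pattern)
        reports[pattern.label()] = _evaluate_pattern(
            table, structure, pattern, get_fold
        )
    return reports


def loocv_evaluate(
    table: pd.DataFrame,
    structure: NetworkStructure,
    pattern: ObservationPattern | str,
    smoothing: float = 0.0,
) -> EvaluationReport:
    if isinstance(pattern, str):
        pattern = ObservationPattern.parse(pattern)
    get_fold = _fold_networks(table, structure, smoothing)
    return _evaluate_pattern(table, structure, pattern, get_fold)


def _evaluate_pattern(table, structure, pattern, get_fold):
    mask = pattern.case_mask(table)
    feats = pattern.features_in(structure)
    records = []
    n_failed = 0
    for i in np.flatnonzero(mask):
        row = table.iloc[i]
        net = get_fold(int(i))
        if net is None:
            n_failed += 1
            continue
        evidence = {f: row[f] for f in feats if not pd.isna(row[f])}
        label, p_high = predict(net, evidence)
        records.append({
            "patient_id": row.get("patient_id", str(i)),
            "true": row[GRADE_COL],
            "predicted": label,
            "p_high": p_high,
        })
    cases = pd.DataFrame(
        records, columns=["patient_id", "true", "predicted", "p_high"]
    )
    n = len(cases)
    n_wrong = int((cases["true"] != cases["predicted"]).sum()) if n else 0
    accuracy = (n - n_wrong) / n if n else float("nan")
    if n and cases["true"].nunique() == 2:
        roc, auc = roc_auc(cases["p_high"].to_numpy(),
                           (cases["true"] == "high").to_numpy())
    else:
        roc, auc = np.empty((0, 2)), float("nan")
    return EvaluationReport(
        pattern.label(), cases, accuracy, n_wrong, n, roc, auc, n_failed
    )


# ---------------------------------------------------------------------------
# ROC / AUC

def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC staircase and trapezoidal AUC from a threshold sweep.

    ``labels`` is boolean (True = positive). Tied scores move diagonally,
    so the trapezoidal area equals the Mann–Whitney statistic with ties
    counted one half. Raises if only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        tp += int(y[i:j].sum())
        fp += int((~y[i:j]).sum())
        points.append((fp / n_neg, tp / n_pos))
        i = j
    pts = np.asarray(points)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return pts, auc


# ---------------------------------------------------------------------------
# feature-subset ablations

def feature_subset_sweep(
    table: pd.DataFrame,
    candidate_features,
    subsets=None,
    include_t1wc: bool = False,
    max_parents: int = 3,
    smoothing: float = 0.0,
) -> pd.DataFrame:
    """LOOCV accuracy for every nonempty subset of candidate features.

    Each subset gets its own K2-learned structure over {grade (+ optional
    enhancement category), subset} on the rows complete for those nodes,
    then a LOOCV evaluation with exactly those features observed. Returns a
    table ranked by accuracy (descending), one row per subset.
    """
    candidates = list(candidate_features)
    if not candidates:
        raise ValueError("candidate feature list must be nonempty")
    if subsets is None:
        import itertools as it
        subsets = [
            combo
            for r in range(1, len(candidates) + 1)
            for combo in it.combinations(candidates, r)
        ]
    rows = []
    for subset in subsets:
        subset = tuple(subset)
        base = (GRADE_COL, T1WC_COL) if include_t1wc else (GRADE_COL,)
        order = base + subset
        complete = table.dropna(subset=list(order))
        structure = k2_search(
            complete, K2Config(order, max_parents=max_parents)
        )
        modalities = {modality_of(f) for f in subset}
        if include_t1wc:
            modalities.add("T1WC")
        pattern = ObservationPattern(frozenset(modalities))
        # evaluate with exactly the subset's features (plus enhancement if
        # requested) as evidence, on rows complete for them
        report = _sweep_evaluate(complete, structure, subset, include_t1wc,
                                 smoothing)
        rows.append({
            "features": " ".join(subset),
            "n_cases": report.n_cases,
            "accuracy": report.accuracy,
            "n_wrong": report.n_wrong,
            "auc": report.auc,
        })
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["accuracy", "features"], ascending=[False, True]
    ).reset_index(drop=True)


def _sweep_evaluate(table, structure, subset, include_t1wc, smoothing):
    get_fold = _fold_networks(table, structure, smoothing)
    feats = list(subset) + ([T1WC_COL] if include_t1wc else [])
    records = []
    for i in range(len(table)):
        row = table.iloc[i]
        net = get_fold(i)
        if net is None:
            continue
        evidence = {f: row[f] for f in feats if not pd.isna(row[f])}
        label, p_high = predict(net, evidence)
        records.append({
            "patient_id": row.get("patient_id", str(i)),
            "true": row[GRADE_COL], "predicted": label, "p_high": p_high,
        })
    cases = pd.DataFrame(
        records, columns=["patient_id", "true", "predicted", "p_high"]
    )
    n = len(cases)
    n_wrong = int((cases["true"] != cases["predicted"]).sum()) if n else 0
    if n and cases["true"].nunique() == 2:
        roc, auc = roc_auc(cases["p_high"].to_numpy(),
                           (cases["true"] == "high").to_numpy())
    else:
        roc, auc = np.empty((0, 2)), float("nan")
    return EvaluationReport("sweep", cases, (n - n_wrong) / n if n else
                            float("nan"), n_wrong, n, roc, auc)
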