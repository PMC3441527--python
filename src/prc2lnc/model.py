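"""High-level model interface: fit the whole classification workflow at once.

:class:`PRC2BindingModel` bundles the pipeline — feature extraction (k-words,
optional PWM hits, LZ76 complexity), t-test feature selection, classifier
training and LOOCV evaluation — behind a statsmodels-flavoured
``Model.fit() -> Results`` interface.  The Results object carries the
selection audit table, consensus motifs, the trained classifier, the CV
report, and renders a text ``summary()``.

Example
-------
>>> from prc2lnc.simulate import SyntheticConfig, generate
>>> from prc2lnc.model import PRC2BindingModel
>>> seqs = generate(SyntheticConfig(seed=7))
>>> res = PRC2BindingModel(seqs, k=6, alpha=0.01).fit(seed=7)
>>> print(res.summary())                           # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classify, evaluate, selection
from .classify import DEFAULT_COST_GRID, ClassifierSpec, TrainedModel
from .features import PWM, FeatureMatrix, build_feature_matrix
from .seqio import (
    NEGATIVE,
    POSITIVE,
    SequenceSet,
    balanced_subsample,
    filter_min_length,
    read_fasta,
)


class PRC2BindingModel:
    """Two-class lncRNA model: PRC2-binding vs PRC2 non-binding.

    Parameters
    ----------
    sequences : SequenceSet
        Labeled sequences (every record tagged positive/negative).
    k : int
        k-word length for the oligonucleotide features (default 6).
    pwms : sequence of PWM
        Optional motif matrices contributing ``pwm:*`` features.
    include_kc : bool
        Include the normalized LZ76 complexity feature.
    alpha : float
        Significance level of the t-test feature selection (0.05 liberal,
        0.01 conservative).
    classifier : str or ClassifierSpec
        One of svm_linear / sda / random_forest / logistic_regression.
    min_score_fraction : float
        PWM hit threshold as a fraction of the attainable score range.
    """

    def __init__(
        self,
        sequences: SequenceSet,
        k: int = 6,
        pwms: Sequence[PWM] = (),
        include_kc: bool = True,
        alpha: float = 0.05,
        classifier: str | ClassifierSpec = "svm_linear",
        min_score_fraction: float = 0.8,
    ) -> None:
        labels = set(sequences.labels)
        if None in labels or not {POSITIVE, NEGATIVE} <= labels:
            raise ValueError("all sequences must be labeled and both classes present")
        self.sequences = sequences
        self.k = k
        self.pwms = list(pwms)
        self.include_kc = include_kc
        self.alpha = alpha
        self.spec = (
            classifier
            if isinstance(classifier, ClassifierSpec)
            else ClassifierSpec(classifier)
        )
        self.min_score_fraction = min_score_fraction
        self._matrix: FeatureMatrix | None = None

    @classmethod
    def from_fasta(
        cls,
        positive_fasta: str | Path,
        negative_fasta: str | Path,
        min_length_exclusive: int = 100,
        equalize: bool = True,
        seed: int = 0,
        **kwargs,
    ) -> "PRC2BindingModel":
        """Build the model from two FASTA files.

        Records of 100 nt or shorter are dropped; when ``equalize``, the
        larger class is randomly subsampled to the size of the smaller one
        (seeded), mirroring the balanced 314 + 314 training design.
        """
        pos = filter_min_length(
            read_fasta(positive_fasta, label=POSITIVE), min_length_exclusive
        )
        neg = filter_min_length(
            read_fasta(negative_fasta, label=NEGATIVE), min_length_exclusive
        )
        if equalize and len(pos) != len(neg):
            n = min(len(pos), len(neg))
            if len(pos) > n:
                pos = balanced_subsample(pos, n, seed)
            else:
                neg = balanced_subsample(neg, n, seed)
        return cls(SequenceSet(list(pos) + list(neg), "training"), **kwargs)

    @property
    def feature_matrix(self) -> FeatureMatrix:
        """The full (pre-selection) feature matrix; built lazily, cached."""
        if self._matrix is None:
            self._matrix = build_feature_matrix(
                self.sequences,
                k=self.k,
                pwms=self.pwms,
                include_kc=self.include_kc,
                min_score_fraction=self.min_score_fraction,
            )
        return self._matrix

    def fit(
        self,
        loocv: bool = True,
        nested_tuning: bool | None = None,
        cost_grid: Sequence[float] = DEFAULT_COST_GRID,
        strict_selection: bool = False,
        seed: int = 0,
    ) -> "PRC2BindingResults":
        """Run selection, train the classifier, and (optionally) LOOCV.

        By default feature selection happens once on the full data before
        LOOCV; ``strict_selection`` re-selects inside every fold instead.
        ``nested_tuning`` (default: on for SVM) re-tunes the SVM cost by
        stratified inner CV within each training set.
        """
        if nested_tuning is None:
            nested_tuning = self.spec.kind == "svm_linear"
        full = self.feature_matrix
        table = selection.select_features(full, alpha=self.alpha)
        names = selection.selected_features(table)
        selected = full.subset_features(names) if names else full

        spec = self.spec
        if spec.kind == "svm_linear" and "C" not in spec.params:
            c = classify.tune_svm_cost(selected, cost_grid, seed=seed)
            spec = ClassifierSpec(spec.kind, {**spec.params, "C": c}, spec.standardize)
        trained = classify.fit(spec, selected, seed=seed)

        report = None
        if loocv:
            if strict_selection:
                report = evaluate.loocv(
                    full, self.spec, nested_tuning=nested_tuning,
                    cost_grid=cost_grid, seed=seed, select_alpha=self.alpha,
                )
            else:
                report = evaluate.loocv(
                    selected, self.spec, nested_tuning=nested_tuning,
                    cost_grid=cost_grid, seed=seed,
                )
        return PRC2BindingResults(self, table, selected, trained, report, seed)


@dataclass
class PRC2BindingResults:
    """Fit artifacts: selection table, trained classifier, CV report."""

    model: PRC2BindingModel
    selection_table: pd.DataFrame
    selected_matrix: FeatureMatrix
    classifier: TrainedModel
    cv: evaluate.CVReport | None
    seed: int

    @property
    def selected_feature_names(self) -> list[str]:
        return selection.selected_features(self.selection_table)

    @property
    def selected_counts(self) -> dict[str, int]:
        return selection.selected_counts_by_namespace(self.selection_table)

    def consensus(self, enriched_class: str = POSITIVE, min_freq: float = 0.1):
        """IUPAC consensus of the selected k-words enriched in one class."""
        return selection.enriched_kmer_consensus(
            self.selection_table, enriched_class, min_freq
        )

    def predict(self, sequences: SequenceSet) -> pd.DataFrame:
        """Classify new sequences; returns prob_positive plus the 0/1 calls
        (columns ``prc2_binding`` / ``prc2_non_binding``, as in a prediction
        table for benchmark transcripts such as HOTAIR fragments)."""
        query = build_feature_matrix(
            sequences,
            k=self.model.k,
            pwms=self.model.pwms,
            include_kc=self.model.include_kc,
            min_score_fraction=self.model.min_score_fraction,
        ).subset_features(self.classifier.feature_names)
        probs = self.classifier.predict_proba(query)
        calls = (probs >= 0.5).astype(int)
        return pd.DataFrame(
            {
                "prob_positive": probs,
                "prc2_binding": calls,
                "prc2_non_binding": 1 - calls,
            },
            index=pd.Index(sequences.ids, name="sample_id"),
        )

    def summary(self) -> str:
        """Human-readable account of the fit."""
        m = self.model
        counts = self.selected_counts
        lines = [
            "PRC2-binding lncRNA classification",
            "=" * 50,
            f"samples:              {len(m.sequences)} "
            f"({sum(l == POSITIVE for l in m.sequences.labels)} positive / "
            f"{sum(l == NEGATIVE for l in m.sequences.labels)} negative)",
            f"feature families:     {m.k}-words"
            + (f", {len(m.pwms)} PWMs" if m.pwms else "")
            + (", KC" if m.include_kc else ""),
            f"selection:            two-sample t-test, alpha = {m.alpha}",
            f"selected features:    {sum(counts.values())} "
            f"(kmer {counts['kmer']} + pwm {counts['pwm']} + kc {counts['kc']})",
            f"classifier:           {self.classifier.spec.kind} "
            f"{self.classifier.spec.params}",
        ]
        pos_cons = self.consensus(POSITIVE)
        neg_cons = self.consensus(NEGATIVE)
        if pos_cons:
            lines.append(f"consensus (positive): {pos_cons.iupac} (n={pos_cons.support})")
        if neg_cons:
            lines.append(f"consensus (negative): {neg_cons.iupac} (n={neg_cons.support})")
        if self.cv is not None:
            met = self.cv.metrics
            lines += [
                "-" * 50,
                "LOOCV performance",
                f"  sensitivity        {met['sensitivity']:.3f}",
                f"  specificity        {met['specificity']:.3f}",
                f"  misclassification  {met['misclassification']:.3f}",
                f"  accuracy           {met['accuracy']:.3f}",
                f"  AUC                {met['auc']:.3f}",
            ]
        return "\n".join(lines)
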