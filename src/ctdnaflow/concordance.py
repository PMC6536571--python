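"""Tissue–plasma RAS concordance with tissue as the reference standard.

Concordance is assessed at the amino-acid-substitution level: a
tissue-mutant patient counts as detected only when *every* tissue RAS
allele is also found in plasma. Extra plasma-only alleles in a
tissue-mutant patient do not flip a concordant call (a patient with two
synchronous primaries carrying different KRAS alleles is concordant
when both appear in plasma).
"""

from __future__ import annotations

from dataclasses import dataclass

from .diagnostics import ConfusionMatrix, MetricWithCI, confusion_metrics

MUTANT = "mutant"
WILD_TYPE = "wild-type"


@dataclass
class PairedRasStatus:
    """RAS status of one patient in both compartments.

    Alleles are amino-acid substitution labels such as ``"KRAS G12D"``;
    an empty set means wild-type in that compartment.
    """

    patient_id: str
    tissue_alleles: frozenset[str]
    plasma_alleles: frozenset[str]

    @property
    def tissue(self) -> str:
        return MUTANT if self.tissue_alleles else WILD_TYPE

    @property
    def plasma(self) -> str:
        return MUTANT if self.plasma_alleles else WILD_TYPE


@dataclass
class ConcordanceResult:
    matrix: ConfusionMatrix
    metrics: dict[str, MetricWithCI]

    @property
    def n_concordant(self) -> int:
        return self.matrix.tp + self.matrix.tn


def ras_concordance(pairs: list[PairedRasStatus], alpha: float = 0.05) -> ConcordanceResult:
    """Confusion matrix and metrics of plasma RAS calls against tissue.

    tp: tissue-mutant with all tissue alleles recovered in plasma;
    fn: tissue-mutant with at least one tissue allele missed;
    tn: wild-type in both compartments;
    fp: tissue wild-type but plasma mutant.
    """
    if not pairs:
        raise ValueError("ras_concordance requires at least one pair")
    tp = fp = tn = fn = 0
    for pair in pairs:
        if pair.tissue_alleles:
            if pair.tissue_alleles <= pair.plasma_alleles:
                tp += 1
            else:
                fn += 1
        else:
            if pair.plasma_alleles:
                fp += 1
            else:
                tn += 1
    matrix = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
    return ConcordanceResult(matrix=matrix, metrics=confusion_metrics(matrix, alpha))
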