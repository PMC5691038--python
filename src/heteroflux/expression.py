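"""Transcriptome integration: GPR mapping, enrichment, regulation calls.

Two-condition replicated expression data are mapped onto reactions via
the boolean gene-protein-reaction rules (AND = enzyme complex → minimum
of the subunit values; OR = isoenzymes → sum, additive enzyme
concentrations), tested for subsystem-level differential expression with
a two-sided Wilcoxon signed-rank test, and combined with sampled flux
distributions into Z-scores

    Z_i^E = (mean(E2_i) - mean(E1_i)) / sqrt(Var(E2_i) + Var(E1_i))
    Z_i^F = (mean(F2_i) - mean(F1_i)) / sqrt(Var(F2_i) + Var(F1_i))

from which reactions are classified as transcriptionally (expression and
flux change together), post-transcriptionally (expression changes, flux
does not) or metabolically (flux changes without expression change)
regulated.  The published method does not print its Z→probability
mapping; here the probabilities are standard-normal CDF composites
(documented interpretation): p_change = 2Φ(|Z|) − 1, and the probability
that two scores move in the same direction is Φ(|Z^E|)·Φ(|Z^F|) +
(1−Φ(|Z^E|))·(1−Φ(|Z^F|)) for aligned signs (mirrored otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import MetabolicModel
from .fba import FluxSampleSet
from .gpr import GprNode


@dataclass
class ExpressionDataset:
    """gene → per-replicate intensity arrays for one condition."""

    intensities: dict[str, np.ndarray]
    condition: str = ""
    normalized: bool = False

    def genes(self) -> list[str]:
        return sorted(self.intensities)

    def n_replicates(self) -> int:
        return len(next(iter(self.intensities.values())))

    def matrix(self, genes: list[str] | None = None) -> np.ndarray:
        genes = genes if genes is not None else self.genes()
        return np.array([self.intensities[g] for g in genes], dtype=float)


@dataclass
class RegulationCall:
    reaction_id: str
    z_expression: float
    z_flux: float
    regulation_class: str   # transcriptional | post_transcriptional | metabolic | none
    probability: float
    scores: dict[str, float] = field(default_factory=dict)


def quantile_normalize(*datasets: ExpressionDataset) -> list[ExpressionDataset]:
    """Quantile-normalize all replicate columns jointly.

    After normalization every column carries the same sorted values (the
    across-column mean distribution); rank ties receive the average of
    the corresponding reference values.
    """
    genes = datasets[0].genes()
    for ds in datasets[1:]:
        if ds.genes() != genes:
            raise ValueError("datasets measure different gene sets")
    columns = []
    owners = []
    for ds in datasets:
        mat = ds.matrix(genes)
        if not np.all(np.isfinite(mat)):
            raise ValueError("missing or non-finite intensities; impute upstream")
        for j in range(mat.shape[1]):
            columns.append(mat[:, j])
            owners.append(ds)
    cols = np.array(columns).T                    # genes x samples
    order = np.argsort(cols, axis=0)
    ranked = np.take_along_axis(cols, order, axis=0)
    reference = ranked.mean(axis=1)
    out = np.empty_like(cols)
    for j in range(cols.shape[1]):
        # average reference values over ties
        ranks = stats.rankdata(cols[:, j], method="average") - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = (reference[lo] + reference[hi]) / 2.0
    results = []
    j = 0
    for ds in datasets:
        n = ds.n_replicates()
        results.append(ExpressionDataset(
            {g: out[i, j:j + n].copy() for i, g in enumerate(genes)},
            condition=ds.condition, normalized=True))
        j += n
    return results


def cv_filter(condition_datasets: list[ExpressionDataset],
              max_cv: float = 0.3) -> list[ExpressionDataset]:
    """Keep genes whose replicate coefficient of variation (sd/mean) is
    below ``max_cv`` in every condition; zero-mean genes are dropped."""
    genes = condition_datasets[0].genes()
    keep = []
    for g in genes:
        ok = True
        for ds in condition_datasets:
            vals = np.asarray(ds.intensities[g], dtype=float)
            if len(vals) < 2:
                raise ValueError("CV filter requires >= 2 replicates")
            mean = vals.mean()
            if mean == 0:
                ok = False
                break
            if vals.std(ddof=1) / mean >= max_cv:
                ok = False
                break
        if ok:
            keep.append(g)
    return [ExpressionDataset({g: ds.intensities[g] for g in keep},
                              condition=ds.condition, normalized=ds.normalized)
            for ds in condition_datasets]


def _reduce_gpr(gpr: GprNode, values: dict[str, float]) -> float | None:
    return gpr.reduce(lambda g: values.get(g),
                      and_op=min, or_op=lambda xs: float(sum(xs)))


def gene_to_reaction_fold_change(model: MetabolicModel,
                                 gene_fold_changes: dict[str, float]
                                 ) -> dict[str, float]:
    """Linear-scale reaction fold changes via GPR (AND = min, OR = sum).

    GPR leaves for unmeasured genes are dropped (an AND over one child is
    that child); reactions with fully unmeasured GPRs are excluded.
    """
    out: dict[str, float] = {}
    for rxn in model.reactions:
        if rxn.gpr is None:
            continue
        fc = _reduce_gpr(rxn.gpr, gene_fold_changes)
        if fc is not None:
            out[rxn.id] = fc
    return out


def reaction_replicate_levels(model: MetabolicModel,
                              dataset: ExpressionDataset) -> dict[str, np.ndarray]:
    """Per-replicate reaction expression levels (GPR applied replicate-wise)
    so reaction-level means and variances are well defined."""
    n = dataset.n_replicates()
    out: dict[str, np.ndarray] = {}
    for rxn in model.reactions:
        if rxn.gpr is None:
            continue
        levels = []
        for k in range(n):
            vals = {g: dataset.intensities[g][k]
                    for g in dataset.intensities}
            v = _reduce_gpr(rxn.gpr, vals)
            if v is None:
                break
            levels.append(v)
        if len(levels) == n:
            out[rxn.id] = np.asarray(levels, dtype=float)
    return out


def subsystem_enrichment(reaction_fold_changes: dict[str, float],
                         subsystem_map: dict[str, str],
                         min_reactions: int = 3,
                         alpha: float = 0.05) -> list[dict]:
    """Two-sided Wilcoxon signed-rank test of log2 reaction fold changes
    against a zero median, per subsystem.

    Uses the exact null distribution for n < 25 and the normal
    approximation with continuity correction otherwise.  Direction is
    the sign of the median log2 fold change.
    """
    groups: dict[str, list[float]] = {}
    for rxn, fc in reaction_fold_changes.items():
        sub = subsystem_map.get(rxn)
        if sub is None or fc <= 0:
            continue
        groups.setdefault(sub, []).append(math.log2(fc))
    rows = []
    for sub in sorted(groups):
        logs = np.asarray(groups[sub])
        if len(logs) < min_reactions:
            continue
        nonzero = logs[logs != 0.0]
        if len(nonzero) == 0:
            p = 1.0
        else:
            mode = "exact" if len(nonzero) < 25 else "approx"
            p = float(stats.wilcoxon(nonzero, alternative="two-sided",
                                     mode=mode, correction=True).pvalue)
        med = float(np.median(logs))
        rows.append({"subsystem": sub, "n": int(len(logs)),
                     "direction": "up" if med > 0 else
                                  ("down" if med < 0 else "flat"),
                     "median_log2fc": med, "p_value": p,
                     "significant": p < alpha})
    return rows


# ---------------------------------------------------------------------------
# file interfaces: gene x sample matrix + sample-annotation sidecar;
# enrichment and regulation-call tables
# ---------------------------------------------------------------------------

def read_expression_matrix(matrix_path, annotation_path
                           ) -> dict[str, ExpressionDataset]:
    """Read a tab-separated gene x sample intensity matrix plus a sidecar
    mapping each sample column to (condition, replicate).

    Matrix: header ``gene<TAB>sample1<TAB>...``; sidecar rows
    ``sample<TAB>condition<TAB>replicate``; '#' lines are comments.
    Returns one dataset per condition with replicates column-ordered.
    """
    import csv as _csv
    import io as _io
    from pathlib import Path as _Path

    def rows(path):
        text = _Path(path).read_text(encoding="utf-8")
        return [r for r in _csv.reader(_io.StringIO(text), delimiter="\t")
                if r and not r[0].lstrip().startswith("#")]

    ann = {}
    for sample, condition, replicate in rows(annotation_path):
        ann[sample] = (condition, int(replicate))
    mat = rows(matrix_path)
    header = mat[0][1:]
    missing = [s for s in header if s not in ann]
    if missing:
        raise ValueError(f"samples without annotation: {missing}")
    by_condition: dict[str, list[int]] = {}
    for j, sample in enumerate(header):
        cond, rep = ann[sample]
        by_condition.setdefault(cond, []).append((rep, j))
    out = {}
    for cond, cols in by_condition.items():
        order = [j for _, j in sorted(cols)]
        out[cond] = ExpressionDataset(
            {row[0]: np.array([float(row[1 + j]) for j in order])
             for row in mat[1:]}, condition=cond)
    return out


def write_enrichment_table(rows: list[dict], path) -> None:
    """Subsystem / direction / p-value table (tab-separated)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("subsystem\tn\tdirection\tmedian_log2fc\tp_value\t"
                 "significant\n")
        for r in rows:
            fh.write(f"{r['subsystem']}\t{r['n']}\t{r['direction']}\t"
                     f"{r['median_log2fc']:.6g}\t{r['p_value']:.6g}\t"
                     f"{r['significant']}\n")


def write_regulation_calls(calls: list["RegulationCall"], path) -> None:
    """Reaction / Z-scores / class / probability table (tab-separated)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("reaction\tz_expression\tz_flux\tclass\tprobability\n")
        for c in calls:
            fh.write(f"{c.reaction_id}\t{c.z_expression:.6g}\t"
                     f"{c.z_flux:.6g}\t{c.regulation_class}\t"
                     f"{c.probability:.6g}\n")


_INF = float("inf")


def _zscore(a2: np.ndarray, a1: np.ndarray) -> float:
    diff = float(np.mean(a2) - np.mean(a1))
    var = float(np.var(a2, ddof=1) + np.var(a1, ddof=1))
    if var == 0.0:
        return 0.0 if diff == 0.0 else math.copysign(_INF, diff)
    return diff / math.sqrt(var)


def regulation_zscores(model: MetabolicModel,
                       e1: ExpressionDataset, e2: ExpressionDataset,
                       f1: FluxSampleSet, f2: FluxSampleSet
                       ) -> dict[str, tuple[float, float]]:
    """(Z^E, Z^F) per reaction present in both the expression mapping and
    the flux sample sets."""
    lev1 = reaction_replicate_levels(model, e1)
    lev2 = reaction_replicate_levels(model, e2)
    if f1.reaction_ids != f2.reaction_ids:
        raise ValueError("flux sample sets cover different reaction sets")
    out: dict[str, tuple[float, float]] = {}
    for rxn_id in sorted(set(lev1) & set(lev2)):
        if rxn_id not in f1.reaction_ids:
            continue
        ze = _zscore(lev2[rxn_id], lev1[rxn_id])
        zf = _zscore(f2.column(rxn_id), f1.column(rxn_id))
        out[rxn_id] = (ze, zf)
    return out


def _p_change(z: float) -> float:
    if math.isinf(z):
        return 1.0
    return 2.0 * stats.norm.cdf(abs(z)) - 1.0


def _p_same_direction(ze: float, zf: float) -> float:
    """Probability the true expression and flux changes share a sign,
    from signed normal CDFs."""
    pe = stats.norm.cdf(ze) if not math.isinf(ze) else (1.0 if ze > 0 else 0.0)
    pf = stats.norm.cdf(zf) if not math.isinf(zf) else (1.0 if zf > 0 else 0.0)
    return float(pe * pf + (1.0 - pe) * (1.0 - pf))


def classify_regulation(zscores: dict[str, tuple[float, float]],
                        threshold: float = 0.9) -> list[RegulationCall]:
    """Score and classify each reaction's regulatory mode.

    transcriptional = p_change(Z^E) · p_same_direction;
    post_transcriptional = p_change(Z^E) · (1 − p_change(Z^F));
    metabolic = (1 − p_change(Z^E)) · p_change(Z^F).
    The top-scoring class is assigned when its score exceeds the
    probability threshold (0.9), otherwise 'none'.
    """
    calls = []
    for rxn_id, (ze, zf) in sorted(zscores.items()):
        pe, pf = _p_change(ze), _p_change(zf)
        scores = {
            "transcriptional": pe * _p_same_direction(ze, zf),
            "post_transcriptional": pe * (1.0 - pf),
            "metabolic": (1.0 - pe) * pf,
        }
        best = max(scores, key=scores.get)
        cls = best if scores[best] > threshold else "none"
        calls.append(RegulationCall(rxn_id, ze, zf, cls, scores[best], scores))
    return calls
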