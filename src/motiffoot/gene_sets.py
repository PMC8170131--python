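"""Driver / non-driver gene classification and expression comparison.

A recurrent mutation is labeled *driver* when MutaGene calls it a
driver or potential driver (under the configured one-or-both-models
rule) AND its CHASMplus score exceeds the cutoff; *passenger* when
every predictor calls it passenger/neutral; otherwise *unresolved*
(including mutations CHASMplus did not score).  A driver gene carries
at least one recurrent driver mutation; a non-driver gene carries only
recurrent passenger mutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association_stats import fisher_exact_2x2, welch_t
from .io_formats import PredictionRecord

log = logging.getLogger(__name__)

DRIVER_CALLS = {"driver", "potential driver"}
PASSENGER_CALLS = {"passenger", "neutral"}


@dataclass(frozen=True)
class MutationLabel:
    mutation_key: str
    gene: str
    label: str  # driver | passenger | unresolved
    recurrence: int


@dataclass
class GeneSet:
    driver_genes: set
    non_driver_genes: set


@dataclass
class ExpressionCompareResult:
    t_stat: float
    t_p: float
    f_stat: float
    f_p: float
    mean_log_expr: dict
    mean_variance: dict
    n_genes: dict


def label_mutations(
    preds: list[PredictionRecord],
    min_recurrence: int = 2,
    chasm_cutoff: float = 0.5,
    mutagene_rule: str = "either",
) -> list[MutationLabel]:
    """Label recurrent mutations as driver / passenger / unresolved.

    mutagene_rule: "either" accepts a driver call from either background
    model (together with the CHASMplus cutoff this still satisfies at
    least two criteria); "both" demands agreement of the two models.
    """
    if mutagene_rule not in {"either", "both"}:
        raise ValueError(f"unknown mutagene_rule {mutagene_rule!r}")
    seen: dict[str, PredictionRecord] = {}
    for p in preds:
        prev = seen.get(p.mutation_key)
        if prev is not None and prev != p:
            raise ValueError(f"conflicting duplicate records for {p.mutation_key!r}")
        seen[p.mutation_key] = p
    out = []
    for p in seen.values():
        if p.recurrence < min_recurrence:
            continue
        calls = (p.mutagene_pancancer, p.mutagene_cohort)
        n_driver_calls = sum(c in DRIVER_CALLS for c in calls)
        mutagene_driver = n_driver_calls >= (1 if mutagene_rule == "either" else 2)
        all_passenger = all(c in PASSENGER_CALLS for c in calls)
        if mutagene_driver and p.chasm_score is not None and p.chasm_score > chasm_cutoff:
            label = "driver"
        elif (
            all_passenger
            and p.chasm_score is not None
            and p.chasm_score <= chasm_cutoff
        ):
            label = "passenger"
        else:
            label = "unresolved"
        out.append(MutationLabel(mutation_key=p.mutation_key, gene=p.gene,
                                 label=label, recurrence=p.recurrence))
    return out


def build_gene_sets(labels: list[MutationLabel]) -> GeneSet:
    """Assign genes to the driver / non-driver sets.

    Genes carrying any unresolved recurrent mutation are excluded from
    both sets so each set's membership is fully determined."""
    by_gene: dict[str, set[str]] = {}
    for lab in labels:
        by_gene.setdefault(lab.gene, set()).add(lab.label)
    driver, non_driver = set(), set()
    for gene, kinds in by_gene.items():
        if "unresolved" in kinds:
            continue
        if "driver" in kinds:
            driver.add(gene)
        elif kinds == {"passenger"}:
            non_driver.add(gene)
    return GeneSet(driver_genes=driver, non_driver_genes=non_driver)


def expression_compare(
    fpkm: pd.DataFrame,
    set1,
    set2,
    variance_test: str = "log-t",
) -> ExpressionCompareResult:
    """Compare expression of two gene sets across samples.

    Per-gene means and variances are taken across samples.  Means are
    compared with a two-tailed Welch t on log2(mean+1).  Variances are
    compared, per ``variance_test``, either with a Welch t on the log
    per-gene variances ("log-t", default) or with a classical
    variance-ratio F on the per-gene log2 mean expression values
    ("f-ratio").
    """
    groups = []
    for name, genes in (("set1", set1), ("set2", set2)):
        genes = list(genes)
        if not genes:
            raise ValueError(f"{name} is empty")
        present = [g for g in genes if g in fpkm.index]
        missing = sorted(set(genes) - set(present))
        if missing:
            log.warning("%s: %d genes absent from the expression table: %s",
                        name, len(missing), missing[:5])
        if not present:
            raise ValueError(f"{name}: no genes present in the expression table")
        sub = fpkm.loc[present].astype(float)
        groups.append((np.log2(sub.mean(axis=1) + 1.0).to_numpy(),
                       sub.var(axis=1, ddof=1).to_numpy(),
                       np.log2(sub.to_numpy() + 1.0)))
    (m1, v1, x1), (m2, v2, x2) = groups
    t_stat, t_p = welch_t(m1, m2)
    if variance_test == "log-t":
        eps = 1e-12
        f_stat, f_p = welch_t(np.log(v1 + eps), np.log(v2 + eps))
    elif variance_test == "f-ratio":
        # classical variance-ratio F on the pooled (gene-centered)
        # log2 expression values of each set
        r1 = (x1 - x1.mean(axis=1, keepdims=True)).ravel()
        r2 = (x2 - x2.mean(axis=1, keepdims=True)).ravel()
        f_stat = float(np.var(r1, ddof=1) / np.var(r2, ddof=1))
        df1, df2 = r1.size - 1, r2.size - 1
        tail = stats.f.sf(f_stat, df1, df2) if f_stat >= 1 else stats.f.cdf(
            f_stat, df1, df2
        )
        f_p = float(min(1.0, 2.0 * tail))
    else:
        raise ValueError(f"unknown variance_test {variance_test!r}")
    return ExpressionCompareResult(
        t_stat=t_stat,
        t_p=t_p,
        f_stat=f_stat,
        f_p=f_p,
        mean_log_expr={"set1": float(m1.mean()), "set2": float(m2.mean())},
        mean_variance={"set1": float(v1.mean()), "set2": float(v2.mean())},
        n_genes={"set1": int(m1.size), "set2": int(m2.size)},
    )


def count_gc_at(mutations) -> tuple[int, int]:
    """Count mutations at G:C versus A:T reference bases."""
    gc = sum(m.ref in "GC" for m in mutations)
    return gc, len(list(mutations)) - gc


def gc_at_mutation_counts(
    set_gc: int, set_at: int, total_gc: int, total_at: int
):
    """2x2 comparison of G:C vs A:T mutation counts in a gene set
    against all remaining genes; complements are computed by
    subtraction from the supplied totals.

    Returns (table, two-tailed Fisher p) with table rows (gene set,
    rest) and columns (G:C, A:T).
    """
    rest_gc = total_gc - set_gc
    rest_at = total_at - set_at
    if min(rest_gc, rest_at) < 0:
        raise ValueError("set counts exceed totals")
    table = np.array([[set_gc, set_at], [rest_gc, rest_at]])
    return table, fisher_exact_2x2(set_gc, set_at, rest_gc, rest_at)
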