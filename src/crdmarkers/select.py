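"""Sequential biomarker filter cascade and marker reporting.

The cascade turns normalized expression into a candidate blood-biomarker
table through nested filters, each a subset of the previous stage:

1. per-protocol differential expression of the 14-day-recovery group against
   baseline (two-group one-way ANOVA, p < 0.001), computed per probe and
   aggregated to genes;
2. intersection of the CW- and CCW-significant genes;
3. fold-change gate: raw-scale FC > 1.2 or < 0.8, in the *same* direction in
   both protocols;
4. exclusion of genes rhythmically expressed (q < 0.05) in any condition;
5. exclusion of known ageing-related genes (case-insensitive symbol match);
6. blood-detectability flag: annotated secreted/extracellular or
   experimentally detected in plasma/serum.

Gene-level aggregation: a gene is significant when at least one of its
probes passes; its fold change is taken from the most significant probe.
"""

from __future__ import annotations

import warnings
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .simulate import STAGES

DEFAULT_DE_ALPHA = 0.001
DEFAULT_FC_LOW = 0.8
DEFAULT_FC_HIGH = 1.2


def differential_expression(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    protocol: str,
    *,
    stage: str = "rec14",
    baseline_stage: str = "baseline",
) -> pd.DataFrame:
    """Per-probe two-group ANOVA of one protocol's recovery group vs baseline.

    Samples are pooled across ZT within each group (time of day treated as
    noise; rhythmic genes are removed downstream). With two groups the
    one-way ANOVA F equals the squared two-sample t statistic. The fold
    change is the raw-scale ratio ``exp(mean ln rec14 - mean ln baseline)``.
    """
    base_ids = design[design["stage"] == baseline_stage]["sample_id"]
    test_ids = design[
        (design["stage"] == stage) & (design["protocol"] == protocol)
    ]["sample_id"]
    if len(base_ids) < 2 or len(test_ids) < 2:
        raise DataError(
            f"need >= 2 samples per group; got baseline={len(base_ids)}, "
            f"{stage}/{protocol}={len(test_ids)}"
        )
    a = matrix[base_ids].to_numpy(float)
    b = matrix[test_ids].to_numpy(float)
    t, p = stats.ttest_ind(b, a, axis=1, equal_var=True)
    log_fc = b.mean(axis=1) - a.mean(axis=1)
    return pd.DataFrame(
        {
            "protocol": protocol,
            "t_stat": t,
            "f_stat": t**2,
            "p_value": np.nan_to_num(p, nan=1.0),
            "log_fc": log_fc,
            "fc": np.exp(log_fc),
        },
        index=pd.Index(matrix.index, name="probe_id"),
    )


def aggregate_de_to_genes(
    de: pd.DataFrame, annotation: Mapping[str, str | None]
) -> pd.DataFrame:
    """Collapse probe-level DE to genes: min p per gene, FC of the top probe.

    Unannotated probes are dropped; multiple probes of one gene count once.
    """
    table = de.copy()
    table["gene"] = [annotation.get(p) for p in table.index]
    table = table[table["gene"].notna() & (table["gene"] != "")]
    table = table.sort_values(["gene", "p_value"], kind="mergesort")
    best = table.groupby("gene", sort=True).first()
    return best[["p_value", "log_fc", "fc"]]


def intersect_de(
    de_a: pd.DataFrame, de_b: pd.DataFrame, alpha: float = DEFAULT_DE_ALPHA
) -> set[str]:
    """Identifiers significant at ``alpha`` in both differential screens."""
    if not 0 < alpha < 1:
        raise ConfigError("alpha must lie in (0, 1)")
    sig_a = set(de_a.index[de_a["p_value"] < alpha])
    sig_b = set(de_b.index[de_b["p_value"] < alpha])
    return sig_a & sig_b


def fold_change_gate(
    fc_a: pd.Series,
    fc_b: pd.Series,
    low: float = DEFAULT_FC_LOW,
    high: float = DEFAULT_FC_HIGH,
) -> set[str]:
    """Genes with concordant fold change beyond the gate in both protocols.

    Keeps a gene only if FC > ``high`` in both or FC < ``low`` in both;
    discordant directions are dropped.
    """
    if not low < 1.0 < high:
        raise ConfigError("fold-change gate requires low < 1 < high")
    shared = fc_a.index.intersection(fc_b.index)
    a, b = fc_a.loc[shared], fc_b.loc[shared]
    keep = ((a > high) & (b > high)) | ((a < low) & (b < low))
    return set(shared[keep])


def rhythmic_genes(
    screens: Mapping[str, pd.DataFrame],
    annotation: Mapping[str, str | None],
    required_stages: Iterable[str] = STAGES,
) -> set[str]:
    """Genes with any rhythmic probe (q < FDR) in any required condition."""
    missing = [s for s in required_stages if s not in screens]
    if missing:
        raise DataError(f"missing rhythmicity screen(s) for condition(s): {missing}")
    out: set[str] = set()
    for stage in required_stages:
        screen = screens[stage]
        flagged = screen.index[screen["rhythmic"].astype(bool)]
        for probe in flagged:
            gene = annotation.get(probe)
            if gene:
                out.add(gene)
    return out


def exclude_rhythmic(
    candidates: Iterable[str],
    screens: Mapping[str, pd.DataFrame],
    annotation: Mapping[str, str | None],
    required_stages: Iterable[str] = STAGES,
) -> set[str]:
    """Drop candidates rhythmically expressed in at least one condition."""
    return set(candidates) - rhythmic_genes(screens, annotation, required_stages)


def exclude_age_related(candidates: Iterable[str], age_genes: Iterable[str]) -> set[str]:
    """Drop known ageing-related genes (case-insensitive symbol match)."""
    candidates = set(candidates)
    age = {g.lower() for g in age_genes}
    if not age:
        warnings.warn("empty ageing-gene list: age filter is a no-op", stacklevel=2)
        return candidates
    return {g for g in candidates if g.lower() not in age}


def flag_blood_detectable(
    candidates: Iterable[str],
    secreted_genes: Iterable[str],
    plasma_genes: Iterable[str],
) -> pd.DataFrame:
    """Flag candidates encoding secreted/extracellular or plasma-detected proteins."""
    secreted = {g.lower() for g in secreted_genes}
    plasma = {g.lower() for g in plasma_genes}
    if not secreted and not plasma:
        warnings.warn("both detectability lists are empty; no gene can be flagged",
                      stacklevel=2)
    detectable = secreted | plasma
    rows = [
        {"gene": g, "blood_detectable": g.lower() in detectable}
        for g in sorted(set(candidates))
    ]
    return pd.DataFrame(rows, columns=["gene", "blood_detectable"])


def read_gene_list(path) -> set[str]:
    """One gene symbol per line; ``#`` starts a comment."""
    out = set()
    with open(path) as fh:
        for line in fh:
            entry = line.split("#", 1)[0].strip()
            if entry:
                out.add(entry)
    return out


def run_selection_cascade(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    annotation: Mapping[str, str | None],
    screens: Mapping[str, pd.DataFrame],
    age_genes: Iterable[str],
    secreted_genes: Iterable[str],
    plasma_genes: Iterable[str],
    *,
    alpha: float = DEFAULT_DE_ALPHA,
    fc_low: float = DEFAULT_FC_LOW,
    fc_high: float = DEFAULT_FC_HIGH,
    consensus_genes: Iterable[str] | None = None,
    protocols: tuple[str, str] = ("CW", "CCW"),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run the full sequential cascade; returns the gene ledger and counts.

    The ledger has one row per gene with its DE p-values and fold changes per
    protocol, every filter flag, and the final blood-candidate flag. The
    counts dict records the size of each nested filter stage.
    """
    proto_a, proto_b = protocols
    de_a = aggregate_de_to_genes(differential_expression(matrix, design, proto_a), annotation)
    de_b = aggregate_de_to_genes(differential_expression(matrix, design, proto_b), annotation)

    genes = de_a.index.union(de_b.index)
    ledger = pd.DataFrame(index=pd.Index(genes, name="gene"))
    ledger[f"de_p_{proto_a.lower()}"] = de_a["p_value"]
    ledger[f"de_p_{proto_b.lower()}"] = de_b["p_value"]
    ledger[f"fc_{proto_a.lower()}"] = de_a["fc"]
    ledger[f"fc_{proto_b.lower()}"] = de_b["fc"]

    sig_both = intersect_de(de_a, de_b, alpha)
    fc_pass = fold_change_gate(
        de_a.loc[list(sig_both), "fc"] if sig_both else de_a["fc"].iloc[:0],
        de_b.loc[list(sig_both), "fc"] if sig_both else de_b["fc"].iloc[:0],
        fc_low,
        fc_high,
    )
    rhythmic = rhythmic_genes(screens, annotation)
    non_rhythmic = fc_pass - rhythmic
    non_age = exclude_age_related(non_rhythmic, age_genes)
    blood = flag_blood_detectable(non_age, secreted_genes, plasma_genes)
    blood_set = set(blood[blood["blood_detectable"]]["gene"])

    ledger["de_both"] = ledger.index.isin(sig_both)
    ledger["fc_gate"] = ledger.index.isin(fc_pass)
    ledger["rhythmic_any_condition"] = ledger.index.isin(rhythmic)
    age_lower = {g.lower() for g in age_genes}
    ledger["age_related"] = [g.lower() in age_lower for g in ledger.index]
    detectable = {g.lower() for g in secreted_genes} | {g.lower() for g in plasma_genes}
    ledger["secreted_or_plasma"] = [g.lower() in detectable for g in ledger.index]
    if consensus_genes is not None:
        consensus = set(consensus_genes)
        ledger["in_consensus_set"] = ledger.index.isin(consensus)
    ledger["blood_candidate"] = ledger.index.isin(blood_set)

    counts = {
        f"de_{proto_a.lower()}": int((de_a["p_value"] < alpha).sum()),
        f"de_{proto_b.lower()}": int((de_b["p_value"] < alpha).sum()),
        "de_both": len(sig_both),
        "fc_pass": len(fc_pass),
        "non_rhythmic": len(non_rhythmic),
        "non_age": len(non_age),
        "blood_candidates": len(blood_set),
    }
    return ledger, counts


def build_marker_report(
    blood_candidates: Iterable[str], consensus_genes: Iterable[str]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Combine both discovery routes into one marker table plus overlap counts.

    One row per gene in the union, flagged by route; counts report the
    consensus-set size, the blood-candidate count and their overlap.
    """
    blood = set(blood_candidates)
    consensus = set(consensus_genes)
    genes = sorted(blood | consensus)
    report = pd.DataFrame(
        {
            "gene": genes,
            "in_consensus_set": [g in consensus for g in genes],
            "blood_candidate": [g in blood for g in genes],
        }
    )
    counts = {
        "consensus_genes": len(consensus),
        "blood_candidates": len(blood),
        "overlap": len(blood & consensus),
    }
    return report, counts


def load_reference_panel() -> pd.DataFrame:
    """Published mouse liver CRD marker panel with per-route flags.

    19 genes, each flagged for membership in the classification consensus
    set and/or the blood-detectable candidate set.
    """
    with resources.files("crdmarkers.data").joinpath("reference_marker_panel.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")
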