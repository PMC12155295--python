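"""TSV/JSON readers and writers for every on-disk format the pipeline uses.

All tabular formats are UTF-8 TSV: TCGA-style matrices ship as TSV and desk
scale needs no binary container.  Every writer has a matching reader and the
pair round-trips exactly (tested), which is what makes run manifests
sufficient to reproduce a run bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .agemap import AgeMap, DivergenceMap, load_age_map, load_divergence_map  # noqa: F401  (re-export)
from .enrichment import DegTable, StratumEnrichmentResult
from .exceptions import ParseError, ValidationError
from .indices import IndexProfile, StagedExpression
from .stages import normalize_stage_label

__all__ = [
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "load_staged_expression",
    "write_age_map",
    "write_divergence_map",
    "load_age_map",
    "load_divergence_map",
    "read_deg_table",
    "write_deg_table",
    "write_profile",
    "read_profile",
    "write_enrichment",
    "write_json",
]


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples matrix: first column ``gene_id``, one column per sample."""
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expression matrix needs a gene_id column and >= 1 sample")
    gene_col = df.columns[0]
    df = df.set_index(gene_col)
    df.index.name = "gene_id"
    try:
        return df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression value ({exc})") from exc


def _full_precision(v: float) -> str:
    # shortest repr that round-trips the float64 exactly
    return repr(float(v))


def write_expression(data: StagedExpression, path) -> None:
    out = data.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format=_full_precision)


def read_metadata(path, normalize: bool = True) -> pd.DataFrame:
    """Read sample metadata: ``sample_id, stage[, patient_id, batch]``.

    Stage labels are normalized to {I, II, III, IV, NAT} unless
    ``normalize=False``; an unmappable label is an error naming the value.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("sample_id", "stage"):
        if col not in df.columns:
            raise ParseError(f"{path}: metadata lacks required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample_id {dup!r}")
    if normalize:
        df["stage"] = [normalize_stage_label(s) for s in df["stage"]]
    return df


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def load_staged_expression(expr_path, meta_path) -> StagedExpression:
    """Load and cross-validate an expression matrix with its sample metadata."""
    values = read_expression(expr_path)
    meta = read_metadata(meta_path)
    stages = meta.set_index("sample_id")["stage"]
    missing = set(values.columns) - set(stages.index)
    if missing:
        raise ValidationError(
            f"{meta_path}: metadata is missing expression sample(s) {sorted(missing)}"
        )
    return StagedExpression(values, stages)


def write_age_map(ages: AgeMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tpai\n")
        for gene in sorted(ages.entries):
            fh.write(f"{gene}\t{ages.entries[gene]}\n")


def write_divergence_map(divergence: DivergenceMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tdnds\n")
        for gene in sorted(divergence.entries):
            fh.write(f"{gene}\t{divergence.entries[gene]!r}\n")


def read_deg_table(path) -> DegTable:
    df = pd.read_csv(
        path, sep="\t", comment="#", float_precision="round_trip",
        dtype={"gene_id": str, "stage": str, "cancer_type": str},
    )
    return DegTable(df)


def write_deg_table(deg: DegTable, path) -> None:
    deg.frame.to_csv(path, sep="\t", index=False, float_format=_full_precision)


def write_profile(profile: IndexProfile, tsv_path, json_path=None) -> None:
    """Write an index profile as TSV with per-sample and per-stage blocks.

    Rows: ``level (sample|stage), id, stage, value``; sample rows carry the
    sample's stage, stage rows repeat the stage id.  An optional JSON mirror
    holds the same content plus gene bookkeeping.
    """
    rows = [
        {"level": "sample", "id": smp, "stage": profile.stages[smp], "value": repr(float(v))}
        for smp, v in profile.per_sample.items()
    ] + [
        {"level": "stage", "id": st, "stage": st, "value": repr(float(v))}
        for st, v in profile.per_stage.items()
    ]
    header = (
        f"# index_kind={profile.index_kind}\taggregation={profile.aggregation}\t"
        f"n_genes_used={profile.n_genes_used}\tn_genes_dropped={profile.n_genes_dropped}\n"
    )
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write(header)
        fh.write("level\tid\tstage\tvalue\n")
        for row in rows:
            fh.write(f"{row['level']}\t{row['id']}\t{row['stage']}\t{row['value']}\n")
    if json_path is not None:
        write_json(profile.to_dict(), json_path)


def read_profile(tsv_path) -> IndexProfile:
    """Read a profile written by :func:`write_profile` back into memory."""
    with open(tsv_path, encoding="utf-8") as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise ParseError(f"{tsv_path}: missing profile header line")
    fields = dict(item.split("=", 1) for item in first[1:].strip().split("\t"))
    df = pd.read_csv(
        tsv_path, sep="\t", comment="#", float_precision="round_trip",
        dtype={"level": str, "id": str, "stage": str},
    )
    samples = df[df["level"] == "sample"]
    stage_rows = df[df["level"] == "stage"]
    return IndexProfile(
        per_sample=pd.Series(
            samples["value"].astype(float).to_numpy(), index=list(samples["id"]), name="index"
        ),
        per_stage=pd.Series(
            stage_rows["value"].astype(float).to_numpy(), index=list(stage_rows["id"]), name="index"
        ),
        index_kind=fields["index_kind"],
        aggregation=fields["aggregation"],
        n_genes_used=int(fields["n_genes_used"]),
        n_genes_dropped=int(fields["n_genes_dropped"]),
        stages=pd.Series(list(samples["stage"]), index=list(samples["id"])),
    )


def write_enrichment(result: StratumEnrichmentResult, tsv_path, json_path=None) -> None:
    table = result.per_stratum.copy()
    table.index.name = "stratum"
    table.to_csv(tsv_path, sep="\t")
    if json_path is not None:
        write_json(result.to_dict(), json_path)


def write_json(obj, path) -> None:
    """Deterministic JSON: sorted keys, stable float repr, trailing newline."""
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, allow_nan=True) + "\n",
        encoding="utf-8",
    )
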