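"""Readers/writers for mutation tables, clinical tables, panels and cohorts.

Formats are plain tab-separated UTF-8 text throughout: MAF (standard
``Hugo_Symbol``/``Tumor_Sample_Barcode`` columns) or long-format TSV for
mutations, one-row-per-patient TSV for clinical data, and one-gene-per-line
text for panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CONTROL, RESPONSE_CATEGORIES, TREATED, CohortDataset

logger = logging.getLogger(__name__)

CLINICAL_REQUIRED = ["sample_id", "arm", "pfs_time", "pfs_event", "os_time", "os_event"]
CLINICAL_OPTIONAL = ["response", "sld", "tmb"]


class FormatError(ValueError):
    """Raised when an input file does not match its declared dialect."""


@dataclass
class MutationTable:
    """Long-format mutation records: one row per retained variant call."""

    records: pd.DataFrame  # columns: sample_id, gene_symbol [, variant_class]
    dialect: str  # "maf" or "long-tsv"
    n_dropped: int = 0


@dataclass
class ClinicalTable:
    """Validated per-patient clinical rows keyed by unique sample_id."""

    rows: pd.DataFrame


def read_mutations(
    path: str | Path,
    dialect: str = "long-tsv",
    variant_filter: list[str] | None = None,
) -> MutationTable:
    """Read mutation calls from a MAF or a long-format (sample, gene) TSV.

    ``variant_filter`` keeps only the listed variant classes (MAF
    ``Variant_Classification`` or an optional third column in long TSV);
    dropped-row counts are logged. Duplicate (sample, gene) pairs are kept
    here and collapsed at matrix construction.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect.lower().replace("_", "-")
    if dialect not in ("maf", "long-tsv"):
        raise ValueError(f"unknown mutation dialect: {dialect!r}")

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.empty:
        raise FormatError(f"{path}: no mutation rows")

    if dialect == "maf":
        for col in ("Hugo_Symbol", "Tumor_Sample_Barcode"):
            if col not in df.columns:
                raise FormatError(f"{path}: MAF is missing required column {col!r}")
        out = pd.DataFrame(
            {
                "sample_id": df["Tumor_Sample_Barcode"].str.strip(),
                "gene_symbol": df["Hugo_Symbol"].str.strip(),
            }
        )
        if "Variant_Classification" in df.columns:
            out["variant_class"] = df["Variant_Classification"].str.strip()
    else:
        if df.shape[1] < 2:
            raise FormatError(f"{path}: long TSV needs at least (sample, gene) columns")
        cols = list(df.columns[:3])
        names = ["sample_id", "gene_symbol", "variant_class"][: len(cols)]
        out = df[cols].copy()
        out.columns = names
        out["sample_id"] = out["sample_id"].str.strip()
        out["gene_symbol"] = out["gene_symbol"].str.strip()

    if (out["gene_symbol"] == "").any() or out["gene_symbol"].isna().any():
        raise FormatError(f"{path}: empty gene symbol in mutation table")

    n_dropped = 0
    if variant_filter is not None:
        if "variant_class" not in out.columns:
            raise FormatError(f"{path}: variant_filter given but no variant class column")
        keep = out["variant_class"].isin(variant_filter)
        n_dropped = int((~keep).sum())
        out = out[keep].reset_index(drop=True)
        logger.info("dropped %d mutation rows failing variant filter", n_dropped)

    return MutationTable(records=out.reset_index(drop=True), dialect=dialect, n_dropped=n_dropped)


def _parse_event(series: pd.Series, name: str) -> np.ndarray:
    vals = pd.to_numeric(series, errors="coerce")
    bad = vals.isna() | ~vals.isin([0, 1])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"column {name!r}, row {row}: expected 0/1, got {series.iloc[row]!r}"
        )
    return vals.astype(int).to_numpy()


def _parse_time(series: pd.Series, name: str) -> np.ndarray:
    vals = pd.to_numeric(series, errors="coerce")
    bad = vals.isna() | (vals <= 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"column {name!r}, row {row}: expected positive number, got {series.iloc[row]!r}"
        )
    return vals.astype(float).to_numpy()


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read and validate the per-patient clinical TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: clinical table is missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample_id {dup!r}")

    out = pd.DataFrame({"sample_id": df["sample_id"].str.strip()})
    arm = df["arm"].str.strip().str.lower()
    bad = ~arm.isin([TREATED, CONTROL])
    if bad.any():
        raise FormatError(
            f"{path}: arm must be '{TREATED}' or '{CONTROL}', "
            f"got {df.loc[bad, 'arm'].iloc[0]!r}"
        )
    out["arm"] = arm
    out["pfs_time"] = _parse_time(df["pfs_time"], "pfs_time")
    out["pfs_event"] = _parse_event(df["pfs_event"], "pfs_event")
    out["os_time"] = _parse_time(df["os_time"], "os_time")
    out["os_event"] = _parse_event(df["os_event"], "os_event")
    if "response" in df.columns:
        resp = df["response"].fillna("NE").str.strip().str.upper()
        bad = ~resp.isin(RESPONSE_CATEGORIES)
        if bad.any():
            raise FormatError(
                f"{path}: unknown response {df.loc[bad, 'response'].iloc[0]!r}"
            )
        out["response"] = resp
    if "sld" in df.columns:
        out["sld"] = pd.to_numeric(df["sld"], errors="coerce").to_numpy()
    if "tmb" in df.columns:
        out["tmb"] = pd.to_numeric(df["tmb"], errors="coerce").to_numpy()
    return ClinicalTable(rows=out.reset_index(drop=True))


def build_dataset(
    mutations: MutationTable,
    clinical: ClinicalTable,
    gene_universe: list[str] | None = None,
    on_unknown_sample: str = "error",
) -> CohortDataset:
    """Assemble a CohortDataset from mutation records and clinical rows.

    The matrix covers the union of observed genes, or exactly
    ``gene_universe`` when given (off-panel symbols are dropped and counted).
    Patients without mutation records get all-zero rows. Mutation samples
    absent from the clinical table raise by default; pass
    ``on_unknown_sample="drop"`` to warn and drop them.
    """
    if on_unknown_sample not in ("error", "drop"):
        raise ValueError("on_unknown_sample must be 'error' or 'drop'")
    clin = clinical.rows
    recs = mutations.records.copy()

    known = set(clin["sample_id"])
    unknown = sorted(set(recs["sample_id"]) - known)
    if unknown:
        if on_unknown_sample == "error":
            raise ValueError(
                f"{len(unknown)} mutation sample(s) absent from clinical table, "
                f"e.g. {unknown[:5]}"
            )
        logger.warning("dropping %d mutation samples absent from clinical table", len(unknown))
        recs = recs[recs["sample_id"].isin(known)]

    if gene_universe is not None:
        universe = [g.strip() for g in gene_universe]
        if len(set(universe)) != len(universe):
            raise ValueError("gene_universe contains duplicates")
        off_panel = sorted(set(recs["gene_symbol"]) - set(universe))
        if off_panel:
            logger.info("dropping %d off-panel gene symbols", len(off_panel))
            recs = recs[recs["gene_symbol"].isin(set(universe))]
        genes = sorted(universe)
    else:
        genes = sorted(set(recs["gene_symbol"]))

    sample_ids = list(clin["sample_id"])
    row_of = {s: i for i, s in enumerate(sample_ids)}
    col_of = {g: j for j, g in enumerate(genes)}
    matrix = np.zeros((len(sample_ids), len(genes)), dtype=np.int8)
    for s, g in zip(recs["sample_id"], recs["gene_symbol"]):
        matrix[row_of[s], col_of[g]] = 1

    return CohortDataset(
        patient_ids=sample_ids,
        genes=genes,
        mutations=matrix,
        arm=clin["arm"].to_numpy(dtype=object),
        pfs_time=clin["pfs_time"].to_numpy(),
        pfs_event=clin["pfs_event"].to_numpy(),
        os_time=clin["os_time"].to_numpy(),
        os_event=clin["os_event"].to_numpy(),
        response=clin["response"].to_numpy(dtype=object) if "response" in clin else None,
        sld=clin["sld"].to_numpy() if "sld" in clin else None,
        tmb=clin["tmb"].to_numpy() if "tmb" in clin else None,
    )


# -- cohort round trip -------------------------------------------------------


def write_cohort(dataset: CohortDataset, mutations_path: str | Path, clinical_path: str | Path) -> None:
    """Write a cohort as long-format mutation TSV plus clinical TSV."""
    rows, cols = np.nonzero(dataset.mutations)
    pd.DataFrame(
        {
            "sample_id": [dataset.patient_ids[i] for i in rows],
            "gene_symbol": [dataset.genes[j] for j in cols],
        }
    ).to_csv(mutations_path, sep="\t", index=False)
    dataset.clinical_frame().to_csv(clinical_path, sep="\t", index=False, float_format="%.12g")


def read_cohort(
    mutations_path: str | Path,
    clinical_path: str | Path,
    gene_universe: list[str] | None = None,
) -> CohortDataset:
    """Read a cohort previously written by :func:`write_cohort`."""
    muts = read_mutations(mutations_path, dialect="long-tsv")
    clin = read_clinical(clinical_path)
    return build_dataset(muts, clin, gene_universe=gene_universe)


def read_gene_list(path: str | Path) -> list[str]:
    """Read a panel file: one gene symbol per line, blanks ignored."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def write_gene_list(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n", encoding="utf-8")
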