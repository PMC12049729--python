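"""Somatic mutation tables: reading, quality filters, annotation, summaries.

The in-memory container is a :class:`MutationTable`: a pandas DataFrame
with one row per coding SNV plus a provenance log of every filter
applied.  Input is a MAF-dialect TSV with a configurable column map
(defaults follow TCGA MC3 names); positions are 0-based indices on the
spliced CDS of the annotated transcript.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic import BASE_CODE, CONTEXTS_96, CONTEXTS_192, context_index_96, context_index_192
from .regions import CodingRegionSet

#: canonical column order of the internal table and of written TSVs
COLUMNS = [
    "sample",
    "transcript",
    "cds_pos",
    "ref",
    "alt",
    "context",
    "context96",
    "consequence",
    "vaf",
    "alt_count",
    "depth",
    "filter",
    "ccf",
    "is_neoantigen",
    "affinity",
    "in_binding_region",
    "in_immunopeptidome",
    "tpm",
]

#: default MAF-dialect column names (MC3-like), internal name -> file column
DEFAULT_COLUMN_MAP = {
    "sample": "Tumor_Sample_Barcode",
    "transcript": "Transcript_ID",
    "cds_pos": "CDS_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "vaf": "VAF",
    "alt_count": "t_alt_count",
    "depth": "t_depth",
    "filter": "FILTER",
    "ccf": "CCF",
    "is_neoantigen": "Is_Neoantigen",
    "affinity": "Affinity_nM",
    "tpm": "TPM",
}

MANDATORY = ["sample", "transcript", "cds_pos", "ref", "alt"]


class SchemaError(ValueError):
    pass


class AnnotationError(ValueError):
    pass


@dataclass
class MutationTable:
    """Ordered collection of somatic SNV records with filter provenance."""

    df: pd.DataFrame
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self):
        for col in COLUMNS:
            if col not in self.df.columns:
                self.df[col] = np.nan
        self.df = self.df[COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def with_df(self, df: pd.DataFrame, step: dict | None = None) -> "MutationTable":
        prov = list(self.provenance)
        if step is not None:
            prov.append(step)
        return MutationTable(df.copy(), prov)

    def sample_slice(self, sample_id: str) -> pd.DataFrame:
        return self.df[self.df["sample"] == sample_id]

    def samples(self) -> list[str]:
        return list(pd.unique(self.df["sample"]))

    def check_unique(self) -> None:
        dup = self.df.duplicated(subset=["sample", "transcript", "cds_pos", "alt"])
        if dup.any():
            raise ValueError(f"{int(dup.sum())} duplicate (sample, transcript, position, alt) records")


def read_mutation_table(path, column_map: dict | None = None) -> MutationTable:
    """Read a MAF-dialect TSV into a :class:`MutationTable`.

    Rows whose ref or alt allele is not a single A/C/G/T base (indels,
    DNVs) are skipped; the skip count is recorded in provenance.
    Unmapped optional fields are left missing.  Raises
    :class:`SchemaError` naming the first missing mandatory column.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep="\t")
    # canonical tables written by this package carry internal names; fall
    # back to those when the mapped MAF column is absent
    for key in COLUMNS:
        if cmap.get(key) not in raw.columns and key in raw.columns:
            cmap[key] = key
    for key in MANDATORY:
        if cmap[key] not in raw.columns:
            raise SchemaError(f"mandatory column {cmap[key]!r} (mapped to {key!r}) missing")
    df = pd.DataFrame(index=raw.index)
    for key, col in cmap.items():
        if col in raw.columns:
            df[key] = raw[col]
    df["sample"] = df["sample"].astype(str)
    snv = df["ref"].astype(str).isin(list("ACGT")) & df["alt"].astype(str).isin(list("ACGT"))
    snv &= df["ref"].astype(str) != df["alt"].astype(str)
    skipped = int((~snv).sum())
    df = df[snv]
    df["cds_pos"] = df["cds_pos"].astype(np.int64)
    table = MutationTable(df)
    table.provenance.append(
        {"step": "read", "path": str(path), "rows": len(df), "skipped_non_snv": skipped}
    )
    return table


def write_mutation_table(table: MutationTable, path, sidecar: bool = True) -> None:
    """Write the canonical TSV plus a JSON provenance sidecar."""
    table.df.to_csv(path, sep="\t", index=False)
    if sidecar:
        with open(f"{path}.provenance.json", "w") as fh:
            json.dump(table.provenance, fh, indent=1, default=str)


def apply_quality_filters(
    table: MutationTable,
    min_alt: int = 3,
    min_vaf: float = 0.01,
    min_depth: int = 15,
    pass_only: bool = True,
) -> MutationTable:
    """Standard somatic-SNV quality filters.

    Keeps records with alt count >= ``min_alt``, VAF >= ``min_vaf`` and
    read depth strictly greater than ``min_depth`` (depth exactly at the
    threshold is removed), optionally requiring FILTER == PASS.  Records
    missing a filtered field are kept.  Idempotent.
    """
    if min_alt < 0 or min_vaf < 0 or min_depth < 0:
        raise ValueError("filter thresholds must be nonnegative")
    df = table.df
    keep = pd.Series(True, index=df.index)
    keep &= df["alt_count"].isna() | (df["alt_count"] >= min_alt)
    keep &= df["vaf"].isna() | (df["vaf"] >= min_vaf)
    keep &= df["depth"].isna() | (df["depth"] > min_depth)
    if pass_only:
        keep &= df["filter"].isna() | (df["filter"] == "PASS")
    step = {
        "step": "quality_filter",
        "min_alt": min_alt,
        "min_vaf": min_vaf,
        "min_depth": min_depth,
        "pass_only": pass_only,
        "removed": int((~keep).sum()),
    }
    return table.with_df(df[keep], step)


def _region_arrays(df: pd.DataFrame, regions: CodingRegionSet):
    """Per-row (up, ref_seq, dn) base codes from the region sequences.

    Rows at CDS edges (no flank) or outside the CDS get code -1.
    """
    n = len(df)
    up = np.full(n, -1, dtype=np.int64)
    rf = np.full(n, -1, dtype=np.int64)
    dn = np.full(n, -1, dtype=np.int64)
    inside = np.zeros(n, dtype=bool)
    tr = df["transcript"].to_numpy()
    ps = df["cds_pos"].to_numpy(dtype=np.int64)
    for tid in pd.unique(tr):
        if tid not in regions:
            continue
        codes = regions[tid].codes.astype(np.int64)
        L = len(codes)
        m = tr == tid
        valid = m & (ps >= 0) & (ps < L)
        inside |= valid
        rf[valid] = codes[ps[valid]]
        flank = valid & (ps >= 1) & (ps < L - 1)
        up[flank] = codes[ps[flank] - 1]
        dn[flank] = codes[ps[flank] + 1]
    return up, rf, dn, inside


def annotate_context(
    table: MutationTable, regions: CodingRegionSet, scheme: int = 192
) -> MutationTable:
    """Annotate trinucleotide mutation contexts on the coding strand.

    Writes both the raw 192-scheme ``context`` and the
    pyrimidine-collapsed ``context96`` columns; ``scheme`` selects which
    one downstream code should treat as primary (192 everywhere except
    HBMR).  Edge positions (no flank within the spliced CDS) get a
    missing context.  A reference-allele mismatch against the CDS
    sequence raises :class:`AnnotationError` listing the offenders.
    """
    if scheme not in (96, 192):
        raise ValueError("scheme must be 96 or 192")
    df = table.df.copy()
    up, rf, dn, inside = _region_arrays(df, regions)
    ref_codes = df["ref"].map(BASE_CODE).to_numpy(dtype=np.int64)
    alt_codes = df["alt"].map(BASE_CODE).to_numpy(dtype=np.int64)
    mismatch = inside & (rf >= 0) & (rf != ref_codes)
    if mismatch.any():
        rows = df.index[mismatch][:20].tolist()
        raise AnnotationError(
            f"{int(mismatch.sum())} records whose ref allele mismatches the CDS sequence "
            f"(first rows: {rows})"
        )
    has_ctx = (up >= 0) & (dn >= 0)
    ctx = np.full(len(df), None, dtype=object)
    ctx96 = np.full(len(df), None, dtype=object)
    if has_ctx.any():
        i192 = context_index_192(up[has_ctx], rf[has_ctx], alt_codes[has_ctx], dn[has_ctx])
        i96 = context_index_96(up[has_ctx], rf[has_ctx], alt_codes[has_ctx], dn[has_ctx])
        ctx[has_ctx] = np.array(CONTEXTS_192, dtype=object)[i192]
        ctx96[has_ctx] = np.array(CONTEXTS_96, dtype=object)[i96]
    df["context"] = ctx
    df["context96"] = ctx96
    return table.with_df(df, {"step": "annotate_context", "scheme": scheme})


def annotate_consequence(table: MutationTable, regions: CodingRegionSet) -> MutationTable:
    """Label each SNV synonymous/nonsynonymous by codon translation.

    A substitution is synonymous iff the mutated codon translates to the
    same amino acid; stop gain/loss is nonsynonymous.  Positions outside
    the CDS (or unknown transcripts) get consequence ``other``.
    """
    from .genetic import CODON_AA

    df = table.df.copy()
    cons = np.full(len(df), "other", dtype=object)
    tr = df["transcript"].to_numpy()
    ps = df["cds_pos"].to_numpy(dtype=np.int64)
    alt_codes = df["alt"].map(BASE_CODE).to_numpy(dtype=np.int64)
    for tid in pd.unique(tr):
        if tid not in regions:
            continue
        codes = regions[tid].codes.astype(np.int64)
        L = len(codes)
        m = (tr == tid) & (ps >= 0) & (ps < L)
        if not m.any():
            continue
        p = ps[m]
        codon_start = (p // 3) * 3
        c = codes[codon_start[:, None] + np.arange(3)]
        codon_idx = c @ np.array([16, 4, 1])
        mult = np.array([16, 4, 1])[p % 3]
        mut_idx = codon_idx + (alt_codes[m] - codes[p]) * mult
        syn = CODON_AA[codon_idx] == CODON_AA[mut_idx]
        cons[m] = np.where(syn, "synonymous", "nonsynonymous")
    df["consequence"] = cons
    return table.with_df(df, {"step": "annotate_consequence"})


def set_neoantigen_flags(
    table: MutationTable,
    affinity_threshold_nm: float = 500.0,
    el_rank_threshold: float | None = None,
    el_rank: pd.Series | None = None,
) -> MutationTable:
    """Derive the neoantigen flag where it was not supplied explicitly.

    An explicitly supplied boolean wins; otherwise a nonsynonymous SNV
    with predicted binding affinity <= 500 nM (or EL %rank <= 2 when a
    rank column is supplied) is flagged.  Synonymous records are never
    neoantigens.
    """
    df = table.df.copy()
    explicit = df["is_neoantigen"].notna()
    derived = df["affinity"] <= affinity_threshold_nm
    if el_rank is not None and el_rank_threshold is not None:
        derived |= pd.Series(np.asarray(el_rank), index=df.index) <= el_rank_threshold
    flag = np.where(explicit, df["is_neoantigen"], derived.fillna(False))
    flag = flag.astype(bool) & (df["consequence"] == "nonsynonymous")
    df["is_neoantigen"] = flag
    return table.with_df(df, {"step": "set_neoantigen_flags", "threshold_nm": affinity_threshold_nm})


def apply_expression_filter(table: MutationTable, min_tpm: float = 1.0) -> MutationTable:
    """Retain the neoantigen flag only for expressed genes (TPM >= 1)."""
    df = table.df.copy()
    expressed = df["tpm"].isna() | (df["tpm"] >= min_tpm)
    df["is_neoantigen"] = df["is_neoantigen"].eq(True) & expressed
    return table.with_df(df, {"step": "expression_filter", "min_tpm": min_tpm})


def summarize_samples(
    table: MutationTable,
    exome_size_mb: float = 38.0,
    hypermutation_threshold: int = 1000,
) -> pd.DataFrame:
    """Per-sample mutation burden summary.

    Returns one row per sample: nonsynonymous (Nobs), synonymous (Sobs)
    and neoantigen (Bobs) counts, TMB (mutations per megabase over the
    configured exome size, default 38 Mb), the TMB group (high >= 20,
    medium 5-20, low < 5) and the hypermutation flag (total mutations
    strictly greater than the threshold).
    """
    if exome_size_mb <= 0:
        raise ValueError("exome size must be positive")
    df = table.df
    grp = df.groupby("sample", sort=True)
    out = pd.DataFrame(
        {
            "n_total": grp.size(),
            "nobs": grp.apply(
                lambda g: int((g["consequence"] == "nonsynonymous").sum()), include_groups=False
            ),
            "sobs": grp.apply(
                lambda g: int((g["consequence"] == "synonymous").sum()), include_groups=False
            ),
            "bobs": grp.apply(
                lambda g: int(g["is_neoantigen"].eq(True).sum()),
                include_groups=False,
            ),
        }
    )
    out["tmb"] = out["n_total"] / exome_size_mb
    out["tmb_group"] = pd.cut(
        out["tmb"], bins=[-np.inf, 5, 20, np.inf], labels=["TMB-low", "TMB-medium", "TMB-high"],
        right=False,
    ).astype(str)
    out["hypermutated"] = out["n_total"] > hypermutation_threshold
    return out.reset_index()
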