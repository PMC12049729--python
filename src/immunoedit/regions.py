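"""Coding-region containers and exhaustive substitution enumeration.

A :class:`CodingRegionSet` holds spliced CDS sequences together with the
genomic exon intervals they were spliced from.  All scores in this
package operate in CDS space (0-based positions on the spliced coding
sequence); the genomic lift is carried for provenance but is optional.

:class:`SubstitutionSpace` enumerates every possible single-base
substitution at every internal CDS position (positions with both
flanking bases) and annotates each with its 192/96 mutation context and
coding consequence.  This enumeration backs the per-context synonymous
probabilities of the codon OE-ratio, the expected counts of HBMR, the
weighted site counts of immune dN/dS, and the mutation simulator's
context-to-site placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic import (
    BASES,
    CODON_AA,
    context_index_96,
    context_index_192,
    encode_sequence,
    translate_codes,
)


@dataclass(frozen=True)
class CodingRegion:
    """One transcript: spliced CDS sequence plus its genomic intervals."""

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # genomic, 0-based half-open
    cds: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if len(self.cds) == 0 or len(self.cds) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {len(self.cds)} not a positive multiple of 3"
            )
        exon_len = sum(e - s for s, e in self.exons)
        if self.exons and exon_len != len(self.cds):
            raise ValueError(
                f"{self.transcript_id}: exon span {exon_len} != CDS length {len(self.cds)}"
            )
        # validates the alphabet as a side effect
        object.__setattr__(self, "_codes", encode_sequence(self.cds))

    @property
    def codes(self) -> np.ndarray:
        return self._codes

    def __len__(self) -> int:
        return len(self.cds)

    def genomic_positions(self) -> np.ndarray:
        """Genomic coordinate of each CDS index (bijective lift)."""
        if not self.exons:
            return np.arange(len(self.cds))
        pos = np.concatenate([np.arange(s, e) for s, e in self.exons])
        if self.strand == "-":
            pos = pos[::-1]
        return pos

    def translate(self) -> str:
        return translate_codes(self.codes)


class CodingRegionSet:
    """Mapping of transcript id -> :class:`CodingRegion`."""

    def __init__(self, regions: list[CodingRegion]):
        self.regions: dict[str, CodingRegion] = {}
        for r in regions:
            if r.transcript_id in self.regions:
                raise ValueError(f"duplicate transcript id {r.transcript_id}")
            self.regions[r.transcript_id] = r

    def __getitem__(self, transcript_id: str) -> CodingRegion:
        return self.regions[transcript_id]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.regions

    def __iter__(self):
        return iter(self.regions.values())

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self)

    @classmethod
    def from_files(cls, fasta_path, bed_path=None) -> "CodingRegionSet":
        """Load spliced CDS sequences from FASTA plus optional BED intervals.

        The FASTA records hold the already-spliced CDS keyed by transcript
        id.  The BED-like TSV (0-based half-open; columns chrom, start,
        end, transcript, [score], strand) supplies the genomic exon
        intervals; without it regions carry an identity lift.
        """
        from pyfaidx import Fasta

        fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
        exon_map: dict[str, list[tuple[str, int, int, str]]] = {}
        if bed_path is not None:
            bed = pd.read_csv(bed_path, sep="\t", header=None, comment="#")
            if bed.shape[1] < 4:
                raise ValueError("BED file needs at least chrom,start,end,name columns")
            for row in bed.itertuples(index=False):
                chrom, start, end, name = row[0], int(row[1]), int(row[2]), str(row[3])
                strand = str(row[5]) if len(row) > 5 else "+"
                exon_map.setdefault(name, []).append((chrom, start, end, strand))
        regions = []
        for name in fa.keys():
            seq = str(fa[name][:])
            if name in exon_map:
                entries = sorted(exon_map[name], key=lambda t: t[1])
                chrom, strand = entries[0][0], entries[0][3]
                exons = tuple((s, e) for _, s, e, _ in entries)
            else:
                chrom, strand, exons = name, "+", ((0, len(seq)),)
            regions.append(CodingRegion(name, chrom, strand, exons, seq))
        return cls(regions)


@dataclass
class RegionAnnotation:
    """Per-CDS-position HLA annotation for a region set.

    ``affinity`` is the aggregated binding affinity in nM (NaN where no
    peptide window covers the position); ``binding`` marks HLA-binding
    regions (aggregated affinity strictly below ``threshold_nm``);
    ``immunopeptidome`` marks positions covered by at least one
    strong-binder peptide window (ON region of immune dN/dS).
    """

    affinity: dict[str, np.ndarray]
    binding: dict[str, np.ndarray]
    immunopeptidome: dict[str, np.ndarray] = field(default_factory=dict)
    threshold_nm: float = 500.0

    def __post_init__(self):
        for tid, aff in self.affinity.items():
            flags = self.binding.get(tid)
            if flags is None or len(flags) != len(aff):
                raise ValueError(f"binding flags missing or mis-sized for {tid}")
            ok = np.isnan(aff) | ((aff < self.threshold_nm) == flags)
            if not ok.all():
                raise ValueError(f"binding flags inconsistent with affinities for {tid}")
        if not self.immunopeptidome:
            self.immunopeptidome = {t: f.copy() for t, f in self.binding.items()}

    def lookup(self, field_name: str, transcript: pd.Series, pos: pd.Series) -> np.ndarray:
        """Vectorised per-mutation lookup of a per-position annotation."""
        source = getattr(self, field_name)
        out = np.full(len(transcript), np.nan if field_name == "affinity" else False)
        out = out.astype(float if field_name == "affinity" else bool)
        tr = np.asarray(transcript)
        ps = np.asarray(pos, dtype=np.int64)
        for tid in np.unique(tr):
            mask = tr == tid
            out[mask] = source[tid][ps[mask]]
        return out


class SubstitutionSpace:
    """All possible single-base substitutions over a coding-region set.

    One row per (internal CDS position, alternate base): arrays
    ``transcript_idx``, ``pos``, ``ref``, ``alt`` (base codes),
    ``ctx192``, ``ctx96`` (context indices) and ``is_syn`` (whether the
    mutated codon translates to the same amino acid; stop gain/loss
    counts as nonsynonymous).
    """

    def __init__(self, regions: CodingRegionSet):
        self.regions = regions
        self.transcript_ids = list(regions.regions)
        t_idx, pos, ref, alt, ctx192, ctx96, is_syn = [], [], [], [], [], [], []
        for ti, region in enumerate(regions):
            codes = region.codes.astype(np.int64)
            L = len(codes)
            p = np.arange(1, L - 1)
            up, rf, dn = codes[p - 1], codes[p], codes[p + 1]
            aa = CODON_AA[codes.reshape(-1, 3) @ np.array([16, 4, 1])]
            codon_of_p = p // 3
            codon_idx = (codes.reshape(-1, 3) @ np.array([16, 4, 1]))[codon_of_p]
            mult = np.array([16, 4, 1])[p % 3]
            # the three non-reference bases at each position, in base-code order
            alt_table = np.array([[b for b in range(4) if b != r] for r in range(4)])
            alts = alt_table[rf]
            for k in range(3):
                a = alts[:, k]
                mut_idx = codon_idx + (a - rf) * mult
                t_idx.append(np.full(len(p), ti, dtype=np.int32))
                pos.append(p)
                ref.append(rf)
                alt.append(a)
                ctx192.append(context_index_192(up, rf, a, dn))
                ctx96.append(context_index_96(up, rf, a, dn))
                is_syn.append(CODON_AA[mut_idx] == aa[codon_of_p])
        order = np.lexsort(
            (np.concatenate(alt), np.concatenate(pos), np.concatenate(t_idx))
        )
        self.transcript_idx = np.concatenate(t_idx)[order]
        self.pos = np.concatenate(pos)[order]
        self.ref = np.concatenate(ref)[order]
        self.alt = np.concatenate(alt)[order]
        self.ctx192 = np.concatenate(ctx192)[order]
        self.ctx96 = np.concatenate(ctx96)[order]
        self.is_syn = np.concatenate(is_syn)[order]
        self.n = len(self.pos)

    def position_flags(self, annotation: RegionAnnotation, field_name: str) -> np.ndarray:
        """Per-row annotation flag looked up at each row's CDS position."""
        out = np.empty(self.n, dtype=bool)
        for ti, tid in enumerate(self.transcript_ids):
            mask = self.transcript_idx == ti
            out[mask] = getattr(annotation, field_name)[tid][self.pos[mask]]
        return out

    def synonymous_probability(self) -> np.ndarray:
        """Per-192-context probability that a substitution is synonymous.

        The fraction of enumerated substitutions with context ``s`` whose
        codon change is synonymous; NaN for contexts absent from the
        region set.
        """
        total = np.bincount(self.ctx192, minlength=192).astype(float)
        syn = np.bincount(self.ctx192, weights=self.is_syn, minlength=192)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, syn / np.maximum(total, 1), np.nan)

    def context_site_counts(self) -> np.ndarray:
        """Number of enumerated substitutions per 192 context."""
        return np.bincount(self.ctx192, minlength=192)


def build_base_strings(codes: np.ndarray) -> np.ndarray:
    """Base codes -> array of single-character base strings."""
    return np.array(list(BASES))[codes]
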