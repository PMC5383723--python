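"""Readers and writers for the on-disk formats the pipeline consumes.

Formats: FASTA (plain and aligned, via Bio.SeqIO), a minimal TSV genotype
table (``unigene_id  pos  sample_A_alleles  sample_B_alleles  quality``),
a read-only VCF subset with two sample GT columns (via pysam), blast
tabular (outfmt6) hit tables, and two-column gene-to-GO-term maps.
All coordinates are 1-based inclusive.  Every rejected record is logged
with file and line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from duosnp.classify import (
    ClassifiedSnp, GenotypeSite, SnpType, iupac_decode,
)
from duosnp.rbh import Hit

logger = logging.getLogger(__name__)

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

GENOTYPE_COLUMNS = [
    "unigene_id", "pos", "sample_A_alleles", "sample_B_alleles", "quality",
]


@dataclass(frozen=True)
class UnigeneRecord:
    """A reference transcript (unigene) with derived length and GC content.

    GC content is computed over non-N bases; gap characters from aligned
    FASTA are ignored for both length bookkeeping and GC.
    """

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_content(self) -> float:
        informative = [b for b in self.sequence if b in "ACGT"]
        if not informative:
            return 0.0
        gc = sum(1 for b in informative if b in "GC")
        return gc / len(informative)


@dataclass
class PipelineConfig:
    """Flat bag of tunables shared by the pipeline stages.

    Same config + same inputs gives byte-identical outputs; ``seed`` feeds
    every random draw in the synthetic generators.
    """

    window_bp: int = 35
    max_snps_in_window: int = 3
    min_quality: float = 2.0
    alpha: float = 0.01
    correction: str = "bonferroni"
    rbh_tie_break: tuple = ("bitscore", "evalue", "identity", "subject")
    max_evalue: Optional[float] = 1e-5
    seed: int = 0

    def __post_init__(self):
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a flat ``key = value`` config file (# comments allowed)."""
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            current = getattr(cls(), key)
            if isinstance(current, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                kwargs[key] = int(value)
            elif isinstance(current, float) or current is None:
                kwargs[key] = float(value)
            elif isinstance(current, tuple):
                kwargs[key] = tuple(v.strip() for v in value.split(","))
            else:
                kwargs[key] = value
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list:
    """Read a (possibly aligned) FASTA into :class:`UnigeneRecord` objects.

    Order is preserved, sequences are uppercased and gap characters kept.
    Duplicate ids raise; an empty file returns an empty list with a warning.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(UnigeneRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        logger.warning("no sequences found in %s", path)
    return records


def write_fasta(records: Iterable[UnigeneRecord], path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Genotype tables

def _parse_allele_pair(text: str, where: str) -> tuple:
    parts = text.strip().upper().replace("|", "/").split("/")
    if len(parts) != 2:
        raise ValueError(f"{where}: allele pair {text!r} is not 'X/Y'")
    return tuple(parts)


def read_genotype_table(path) -> list:
    """Read the minimal TSV genotype dialect into :class:`GenotypeSite` rows.

    Rows with alleles outside ACGT are rejected and logged; a position < 1
    is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    sites = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        where = f"{path}:{i}"
        pos = int(row.pos)
        if pos < 1:
            raise ValueError(f"{where}: position {pos} < 1")
        try:
            site = GenotypeSite(
                unigene_id=row.unigene_id,
                pos=pos,
                alleles_a=_parse_allele_pair(row.sample_A_alleles, where),
                alleles_b=_parse_allele_pair(row.sample_B_alleles, where),
                quality=float(row.quality) if pd.notna(row.quality) else None,
            )
        except ValueError as exc:
            logger.warning("%s: rejected record (%s)", where, exc)
            continue
        sites.append(site)
    return sites


def write_genotype_table(sites: Sequence[GenotypeSite], path) -> None:
    df = pd.DataFrame(
        {
            "unigene_id": [s.unigene_id for s in sites],
            "pos": [s.pos for s in sites],
            "sample_A_alleles": ["/".join(s.alleles_a) for s in sites],
            "sample_B_alleles": ["/".join(s.alleles_b) for s in sites],
            "quality": [s.quality for s in sites],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_vcf_genotypes(path) -> list:
    """Read a two-sample VCF (GT fields) into :class:`GenotypeSite` rows.

    Only biallelic-by-genotype SNV records with two called diploid samples
    are used; anything else is logged and skipped.  QUAL maps to quality.
    """
    import pysam

    sites = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 2:
            raise ValueError(f"{path}: expected exactly 2 samples, "
                             f"found {len(samples)}")
        for rec in vcf:
            pairs = []
            ok = True
            for sample in samples:
                gt = rec.samples[sample].alleles
                if gt is None or len(gt) != 2 or any(a is None for a in gt):
                    ok = False
                    break
                if any(len(a) != 1 or a.upper() not in "ACGT" for a in gt):
                    ok = False
                    break
                pairs.append(tuple(a.upper() for a in gt))
            if not ok:
                logger.warning("%s:%s skipped non-SNV/uncalled record",
                               rec.chrom, rec.pos)
                continue
            sites.append(GenotypeSite(
                unigene_id=rec.chrom, pos=rec.pos,
                alleles_a=pairs[0], alleles_b=pairs[1],
                quality=rec.qual,
            ))
    return sites


# ---------------------------------------------------------------------------
# Hit tables (blast outfmt6)

def read_hit_table(path) -> list:
    """Read a 12-column blast tabular file into :class:`Hit` objects."""
    hits = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"found {len(fields)}")
            hits.append(Hit(
                query=fields[0], subject=fields[1],
                identity_pct=float(fields[2]), length=int(fields[3]),
                mismatch=int(fields[4]), gapopen=int(fields[5]),
                qstart=int(fields[6]), qend=int(fields[7]),
                sstart=int(fields[8]), send=int(fields[9]),
                evalue=float(fields[10]), bitscore=float(fields[11]),
            ))
    return hits


def write_hit_table(hits: Sequence[Hit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(str(v) for v in (
                h.query, h.subject, h.identity_pct, h.length, h.mismatch,
                h.gapopen, h.qstart, h.qend, h.sstart, h.send,
                h.evalue, h.bitscore)) + "\n")


# ---------------------------------------------------------------------------
# Classified-SNP tables

def write_classified_table(classified: Sequence[ClassifiedSnp], path) -> None:
    df = pd.DataFrame({
        "unigene_id": [c.site.unigene_id for c in classified],
        "pos": [c.site.pos for c in classified],
        "type": [c.snp_type.value for c in classified],
        "iupac_A": [c.iupac_a for c in classified],
        "iupac_B": [c.iupac_b for c in classified],
    })
    df.to_csv(path, sep="\t", index=False)


def read_classified_table(path) -> list:
    """Rebuild classified SNPs from the TSV; allele pairs are recovered
    from the IUPAC codes (quality is not round-tripped)."""
    df = pd.read_csv(path, sep="\t", dtype={"unigene_id": str})
    out = []
    for row in df.itertuples(index=False):
        pair_a = tuple(sorted(iupac_decode(row.iupac_A)))
        pair_b = tuple(sorted(iupac_decode(row.iupac_B)))
        site = GenotypeSite(
            unigene_id=row.unigene_id, pos=int(row.pos),
            alleles_a=pair_a * 2 if len(pair_a) == 1 else pair_a,
            alleles_b=pair_b * 2 if len(pair_b) == 1 else pair_b,
        )
        out.append(ClassifiedSnp(site=site, snp_type=SnpType(row.type),
                                 iupac_a=row.iupac_A, iupac_b=row.iupac_B))
    return out


# ---------------------------------------------------------------------------
# GO maps

def read_go_map(path) -> dict:
    """Read a two-column ``gene_id<TAB>GO:NNNNNNN`` file into gene->terms."""
    gene2terms: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            gene, term = fields
            gene2terms.setdefault(gene, set()).add(term)
    return gene2terms


def write_go_map(gene2terms: dict, path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(gene2terms):
            for term in sorted(gene2terms[gene]):
                fh.write(f"{gene}\t{term}\n")
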