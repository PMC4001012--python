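"""Readers and writers for the standard formats the pipeline touches.

VCF is read through :mod:`cyvcf2` and GTF through :mod:`gffutils`; writers
emit plain text directly (VCF 4.2 with GT only, Ensembl-dialect GTF, TSV,
BED6).  Internal coordinates are 1-based inclusive; only BED output converts
to 0-based half-open.

The allele-A dosage convention: by default allele A is the VCF REF allele,
so a fully homozygous-REF VCF reads as an all-2 matrix.  PLINK-style text
tables carry their own A-allele column, which is taken as allele A as-is.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeDataset, TranscriptModel, VariantRecord

logger = logging.getLogger(__name__)

CATEGORY_LETTERS = "abcdefghi"


class ParseError(ValueError):
    """A malformed record in an input file."""


class LabellingError(ValueError):
    """A sample present in the genotype file has no population label."""


# ---------------------------------------------------------------------------
# population labels and gene list
# ---------------------------------------------------------------------------

def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample_id<TAB>population`` file (no header)."""
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if frame.shape[1] < 2:
        raise ParseError(f"{path}: labels file needs two tab-separated columns")
    labels = dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))
    if len(labels) != len(frame):
        raise ParseError(f"{path}: duplicated sample id in labels file")
    return labels


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, pop in labels.items():
            fh.write(f"{sample}\t{pop}\n")


def read_gene_list(path: str | Path) -> dict[str, str]:
    """Read a ``transcript_or_gene_id<TAB>category`` target list.

    Categories are the nine epigenetic-machinery group letters a-i.
    Duplicated ids and unknown letters are rejected.
    """
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if frame.shape[1] < 2:
        raise ParseError(f"{path}: gene list needs two tab-separated columns")
    mapping: dict[str, str] = {}
    for line_no, (ident, cat) in enumerate(zip(frame.iloc[:, 0], frame.iloc[:, 1]), 1):
        if cat not in CATEGORY_LETTERS:
            raise ParseError(f"{path} row {line_no}: unknown category {cat!r} (expected a-i)")
        if ident in mapping:
            raise ParseError(f"{path} row {line_no}: duplicated id {ident!r}")
        mapping[ident] = cat
    return mapping


def write_gene_list(mapping: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ident, cat in mapping.items():
            fh.write(f"{ident}\t{cat}\n")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(
    path: str | Path,
    format: str = "vcf",
    labels_path: str | Path | None = None,
    labels: dict[str, str] | None = None,
) -> GenotypeDataset:
    """Read genotypes into a :class:`GenotypeDataset`.

    Parameters
    ----------
    path : path
        Genotype file. ``format="vcf"`` expects VCF 4.x with GT calls
        (phased or unphased; phase is discarded); ``format="plink_text"``
        expects the tab-separated dosage table written by
        :func:`write_plink_text`.
    labels_path, labels :
        Population labels, either as a file (``sample<TAB>population``) or
        an in-memory mapping. Every sample in the genotype file must be
        labelled.
    """
    if labels is None:
        if labels_path is None:
            raise ValueError("either labels_path or labels is required")
        labels = read_labels(labels_path)
    if format == "vcf":
        variants, sample_ids, calls = _read_vcf(Path(path))
    elif format == "plink_text":
        variants, sample_ids, calls = _read_plink_text(Path(path))
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    missing_labels = [s for s in sample_ids if s not in labels]
    if missing_labels:
        raise LabellingError(
            f"{len(missing_labels)} samples lack a population label "
            f"(first: {missing_labels[:3]})"
        )
    dataset = GenotypeDataset(
        variants=variants,
        sample_ids=sample_ids,
        population_of={s: labels[s] for s in sample_ids},
        calls=calls,
    )
    _flag_all_missing(dataset)
    return dataset


def _flag_all_missing(dataset: GenotypeDataset) -> None:
    # retained but flagged: downstream frequency code treats them as undefined
    for pop in dataset.populations:
        rows = dataset.sample_rows(pop)
        n_all_missing = int(np.sum(np.all(dataset.calls[rows] == MISSING, axis=0)))
        if n_all_missing:
            logger.warning(
                "%d variants are 100%% missing in population %s; "
                "their frequencies are undefined", n_all_missing, pop,
            )


def _read_vcf(path: Path):
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)  # gt_types: 0=homREF,1=het,2=homALT,3=missing
    sample_ids = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for v in vcf:
        if len(v.ALT) != 1:
            site = v.ID or f"{v.CHROM}:{v.POS}"
            raise ParseError(
                f"{path}: site {site} is not biallelic (ALT={','.join(v.ALT) or '.'})"
            )
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        try:
            variants.append(
                VariantRecord(vid, v.CHROM, v.POS, v.REF, v.ALT[0])
            )
        except ValueError as exc:
            raise ParseError(f"{path}: site {vid}: {exc}") from exc
        gt = np.asarray(v.gt_types)
        dosage = (2 - gt).astype(np.int8)  # copies of REF = allele A
        dosage[gt == 3] = MISSING
        columns.append(dosage)
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(sample_ids), 0), dtype=np.int8)
    )
    return variants, sample_ids, calls


def write_vcf(dataset: GenotypeDataset, path: str | Path) -> None:
    """Write a minimal VCF 4.2 (GT only) under the allele_A = REF convention."""
    chroms = list(dict.fromkeys(v.chromosome for v in dataset.variants))
    gt_of = {2: "0/0", 1: "0/1", 0: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset.sample_ids)
            + "\n"
        )
        for j, v in enumerate(dataset.variants):
            gts = "\t".join(gt_of[int(d)] for d in dataset.calls[:, j])
            fh.write(
                f"{v.chromosome}\t{v.position}\t{v.variant_id}\t"
                f"{v.allele_A}\t{v.allele_B}\t.\t.\t.\tGT\t{gts}\n"
            )


_PLINK_FIXED = ["variant_id", "chromosome", "position", "allele_A", "allele_B"]


def _read_plink_text(path: Path):
    frame = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    if list(frame.columns[:5]) != _PLINK_FIXED:
        raise ParseError(
            f"{path}: expected leading columns {_PLINK_FIXED}, got {list(frame.columns[:5])}"
        )
    sample_ids = list(frame.columns[5:])
    variants = []
    for row in frame.itertuples(index=False):
        try:
            variants.append(
                VariantRecord(row.variant_id, row.chromosome, int(row.position),
                              row.allele_A, row.allele_B)
            )
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    dosages = frame.iloc[:, 5:].to_numpy(dtype=float)
    calls = np.full(dosages.shape, MISSING, dtype=np.int8)
    ok = ~np.isnan(dosages)
    if not np.isin(dosages[ok], (0, 1, 2)).all():
        raise ParseError(f"{path}: dosages must be 0, 1, 2 or NA")
    calls[ok] = dosages[ok].astype(np.int8)
    return variants, sample_ids, calls.T.copy()


def write_plink_text(dataset: GenotypeDataset, path: str | Path) -> None:
    """Write the PLINK-style text dosage table (variants as rows)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_PLINK_FIXED + dataset.sample_ids) + "\n")
        for j, v in enumerate(dataset.variants):
            dos = [
                "NA" if d == MISSING else str(int(d)) for d in dataset.calls[:, j]
            ]
            fh.write(
                f"{v.variant_id}\t{v.chromosome}\t{v.position}\t"
                f"{v.allele_A}\t{v.allele_B}\t" + "\t".join(dos) + "\n"
            )


# ---------------------------------------------------------------------------
# transcripts (GTF)
# ---------------------------------------------------------------------------

_UTR5_TYPES = {"five_prime_utr", "5UTR"}
_UTR3_TYPES = {"three_prime_utr", "3UTR"}


def read_transcripts(path: str | Path) -> list[TranscriptModel]:
    """Parse a GTF (Ensembl-dialect attributes) into transcript models.

    One model per ``transcript_id``; the span is the min/max over the
    transcript's features (a declared ``transcript`` feature wins, and exons
    outside a declared span raise). Exon features are mandatory.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if "transcript_id" not in feat.attributes:
            continue
        tid = feat.attributes["transcript_id"][0]
        info = per_tx.setdefault(
            tid,
            {"gene_id": feat.attributes.get("gene_id", [tid])[0],
             "chromosome": feat.seqid, "strand": feat.strand,
             "exons": [], "utr5": [], "utr3": [], "span": None,
             "lo": feat.start, "hi": feat.end},
        )
        info["lo"] = min(info["lo"], feat.start)
        info["hi"] = max(info["hi"], feat.end)
        if feat.featuretype == "transcript":
            info["span"] = (feat.start, feat.end)
        elif feat.featuretype == "exon":
            info["exons"].append((feat.start, feat.end))
        elif feat.featuretype in _UTR5_TYPES:
            info["utr5"].append((feat.start, feat.end))
        elif feat.featuretype in _UTR3_TYPES:
            info["utr3"].append((feat.start, feat.end))
    models = []
    for tid, info in per_tx.items():
        if not info["exons"]:
            raise ParseError(f"{path}: transcript {tid} has no exon features")
        if info["span"] is not None:
            start, end = info["span"]
            for a, b in info["exons"]:
                if a < start or b > end:
                    raise ParseError(
                        f"{path}: transcript {tid}: exon ({a},{b}) outside "
                        f"declared span ({start},{end})"
                    )
        else:
            start, end = info["lo"], info["hi"]
        models.append(
            TranscriptModel(
                gene_id=info["gene_id"], transcript_id=tid,
                chromosome=info["chromosome"],
                strand=info["strand"] if info["strand"] in "+-" else "+",
                start=start, end=end, exons=sorted(info["exons"]),
                utr5=sorted(info["utr5"]), utr3=sorted(info["utr3"]),
            )
        )
    models.sort(key=lambda t: (t.chromosome, t.start, t.transcript_id))
    return models


def write_gtf(transcripts: list[TranscriptModel], path: str | Path) -> None:
    """Write transcript/exon/UTR features as Ensembl-dialect GTF."""

    def line(t: TranscriptModel, feature: str, start: int, end: int) -> str:
        attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
        return (
            f"{t.chromosome}\tepidiff\t{feature}\t{start}\t{end}\t.\t"
            f"{t.strand}\t.\t{attrs}\n"
        )

    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(line(t, "transcript", t.start, t.end))
            for a, b in t.exons:
                fh.write(line(t, "exon", a, b))
            for a, b in t.utr5:
                fh.write(line(t, "five_prime_utr", a, b))
            for a, b in t.utr3:
                fh.write(line(t, "three_prime_utr", a, b))


# ---------------------------------------------------------------------------
# BED / report tables
# ---------------------------------------------------------------------------

def write_bed6(
    rows: list[tuple[str, int, str, str]], path: str | Path
) -> None:
    """Write (chromosome, 1-based position, name, strand) SNP rows as BED6."""
    with open(path, "w") as fh:
        for chrom, pos, name, strand in rows:
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{name}\t0\t{strand}\n")


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a report table as TSV with a header row."""
    frame.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chromosome": str})
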