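"""Amplicon read processing: demultiplex, consensus-validate, extract the
mutagenized region, translate, and count motifs per sorted bin.

Each read is expected to be a fixed-architecture amplicon::

    [upstream flank with a 3-nt bin barcode] [15-nt mutagenized region]
    [15-nt anchor] [downstream flank]

The filters are applied in a fixed order — barcode, consensus, anchor,
translation — and each discarded read is charged to exactly the first rule it
fails, so the discard ledger partitions the input.  Matching is exact
(zero-mismatch) throughout: a read differing from the consensus anywhere
outside the barcode slot and the mutagenized region is discarded, as is any
read whose region contains a stop codon or an ambiguous base.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .genetics import CODON_TO_AA, STOP_CODONS

BIN_IDS = ("B1", "B2", "B3", "B4")

#: Discard-rule labels, in filter order.
RULE_BARCODE = "barcode-mismatch"
RULE_CONSENSUS = "consensus-mismatch"
RULE_NO_ANCHOR = "no-anchor"
RULE_STOP = "stop-codon"
RULE_AMBIGUOUS = "ambiguous-base"
DISCARD_RULES = (RULE_BARCODE, RULE_CONSENSUS, RULE_NO_ANCHOR, RULE_STOP, RULE_AMBIGUOUS)

REJECT = None


@dataclass(frozen=True)
class AmpliconTemplate:
    """Fixed read architecture.

    ``upstream`` is everything 5' of the mutagenized region, with a 3-nt
    barcode slot starting at ``barcode_offset`` (0-based; the slot's content
    in the template string is a placeholder).  ``anchor`` is the 15-nt
    sequence immediately 3' of the region, used to locate it; ``downstream``
    is everything 3' of the anchor.  All coordinates are 0-based half-open.
    """

    upstream: str
    anchor: str
    downstream: str
    barcode_offset: int
    region_length: int = 15

    def __post_init__(self) -> None:
        if self.region_length != 15:
            raise ValueError("region_length is fixed at 15")
        if len(self.anchor) != 15:
            raise ValueError("anchor must be exactly 15 nt")
        if not (0 <= self.barcode_offset <= len(self.upstream) - 3):
            raise ValueError("barcode slot must lie inside the upstream flank")
        if self.anchor in self.upstream:
            raise ValueError(
                "anchor occurs in the upstream flank; first-match extraction "
                "would be ambiguous"
            )

    @property
    def region_start(self) -> int:
        return len(self.upstream)

    @property
    def region_end(self) -> int:
        return self.region_start + self.region_length

    @property
    def read_length(self) -> int:
        return len(self.upstream) + self.region_length + len(self.anchor) + len(self.downstream)

    def build_read(self, barcode: str, region: str) -> str:
        """Assemble an error-free amplicon read."""
        if len(barcode) != 3:
            raise ValueError("barcode must be 3 nt")
        if len(region) != self.region_length:
            raise ValueError(f"region must be {self.region_length} nt")
        up = (
            self.upstream[: self.barcode_offset]
            + barcode
            + self.upstream[self.barcode_offset + 3 :]
        )
        return up + region + self.anchor + self.downstream


#: Default architecture: a 6-nt adapter stub, the barcode slot, the 3' end of
#: the ubiquitin ORF (…LRGG, whose scarless cleavage exposes the neo-N
#: terminus), the mutagenized P1-P5 region, a 15-nt anchor encoding the ISDFI
#: template context, and the start of the downstream reporter ORF.
DEFAULT_TEMPLATE = AmpliconTemplate(
    upstream="ACGTGA" + "NNN" + "CTGCGTGGTGGT",
    anchor="ATTAGCGATTTCATT",  # I S D F I
    downstream="AGCAAAGGAGAAGAACTG",
    barcode_offset=6,
)

DEFAULT_BARCODES: dict[str, str] = {"B1": "AAC", "B2": "CCG", "B3": "GGT", "B4": "TTA"}


def demultiplex(read: str, template: AmpliconTemplate, barcode_map: dict[str, str]):
    """Assign a read to a bin by exact barcode match, or REJECT (None).

    ``barcode_map`` maps bin id -> 3-nt barcode; the four barcodes must be
    distinct.
    """
    inverse = {v: k for k, v in barcode_map.items()}
    if len(inverse) != len(barcode_map):
        raise ValueError("barcodes must be distinct")
    slot = read[template.barcode_offset : template.barcode_offset + 3]
    if len(slot) < 3:
        return REJECT
    return inverse.get(slot, REJECT)


def validate_consensus(read: str, template: AmpliconTemplate) -> bool:
    """True iff every base outside the barcode slot and the mutagenized
    region equals the template exactly (zero-mismatch policy).  A read of the
    wrong length fails."""
    if len(read) != template.read_length:
        return False
    off = template.barcode_offset
    up = template.upstream
    if read[:off] != up[:off]:
        return False
    if read[off + 3 : len(up)] != up[off + 3 :]:
        return False
    return read[template.region_end :] == template.anchor + template.downstream


def extract_region(read: str, template: AmpliconTemplate):
    """Return the 15 nt immediately 5' of the first exact anchor occurrence,
    or REJECT (None) when the anchor is absent or has fewer than 15 nt before
    it."""
    idx = read.find(template.anchor)
    if idx < template.region_length:
        return REJECT
    return read[idx - template.region_length : idx]


def translate_and_filter(region: str):
    """Translate a 15-nt region into a 5-residue motif.

    Returns ``(motif, None)`` on success or ``(None, rule)`` where rule is
    ``stop-codon`` (any of TAG/TAA/TGA) or ``ambiguous-base`` (a codon with a
    non-ACGT character).  Codons are checked left to right; the first failing
    codon decides the rule.
    """
    if len(region) != 15:
        raise ValueError("region must be exactly 15 nt")
    residues = []
    for i in range(0, 15, 3):
        codon = region[i : i + 3]
        if codon in STOP_CODONS:
            return None, RULE_STOP
        aa = CODON_TO_AA.get(codon)
        if aa is None:
            return None, RULE_AMBIGUOUS
        residues.append(aa)
    return "".join(residues), None


@dataclass
class BinCountTable:
    """Per-genotype motif x bin read counts plus the discard ledger."""

    genotype: str
    counts: pd.DataFrame  # columns: motif, count_b1..count_b4
    ledger: dict[str, int] = field(default_factory=dict)
    raw_total: int = 0

    @property
    def bin_totals(self) -> list[int]:
        return [int(self.counts[f"count_{b.lower()}"].sum()) for b in BIN_IDS]

    @property
    def kept_total(self) -> int:
        return int(sum(self.bin_totals))

    def reconciles(self) -> bool:
        """Accounting identity: kept + discarded == raw."""
        return self.kept_total + sum(self.ledger.values()) == self.raw_total

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# genotype={self.genotype}\traw_total={self.raw_total}\n")
            self.counts.to_csv(fh, sep="\t", index=False)
        ledger = pd.DataFrame(
            {"rule": list(DISCARD_RULES), "count": [self.ledger.get(r, 0) for r in DISCARD_RULES]}
        )
        ledger.to_csv(path.with_suffix(".ledger.tsv"), sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BinCountTable":
        path = Path(path)
        with open(path) as fh:
            header = fh.readline()
            meta = dict(
                item.split("=", 1) for item in header.lstrip("# ").strip().split("\t")
            )
            counts = pd.read_csv(fh, sep="\t")
        ledger: dict[str, int] = {}
        ledger_path = path.with_suffix(".ledger.tsv")
        if ledger_path.exists():
            ldf = pd.read_csv(ledger_path, sep="\t")
            ledger = dict(zip(ldf["rule"], ldf["count"].astype(int)))
        return cls(
            genotype=meta.get("genotype", "NA"),
            counts=counts,
            ledger=ledger,
            raw_total=int(meta.get("raw_total", 0)),
        )


def iter_fastq_sequences(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a plain or gzipped FASTQ file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                yield line.rstrip("\n")


def count_motifs(
    reads: Iterable[str],
    template: AmpliconTemplate,
    barcode_map: dict[str, str] | None = None,
    genotype: str = "NA",
) -> BinCountTable:
    """Run the full filter cascade over pooled reads and tabulate kept motifs
    per bin.

    Filter order is fixed: demultiplex -> consensus -> anchor/extract ->
    translate.  Each read is charged to exactly one discard rule (first
    failure wins), so ``ledger + kept == raw``.  Counting is independent of
    read order.
    """
    barcode_map = dict(DEFAULT_BARCODES if barcode_map is None else barcode_map)
    inverse = {v: k for k, v in barcode_map.items()}
    if len(inverse) != len(barcode_map):
        raise ValueError("barcodes must be distinct")
    off = template.barcode_offset
    tallies: Counter = Counter()
    ledger: Counter = Counter()
    raw = 0
    for read in reads:
        raw += 1
        bin_id = inverse.get(read[off : off + 3])
        if bin_id is None:
            ledger[RULE_BARCODE] += 1
            continue
        if not validate_consensus(read, template):
            ledger[RULE_CONSENSUS] += 1
            continue
        region = extract_region(read, template)
        if region is None:
            ledger[RULE_NO_ANCHOR] += 1
            continue
        motif, rule = translate_and_filter(region)
        if motif is None:
            ledger[rule] += 1
            continue
        tallies[(motif, bin_id)] += 1
    motifs = sorted({m for m, _ in tallies})
    counts = pd.DataFrame({"motif": motifs})
    for b in BIN_IDS:
        counts[f"count_{b.lower()}"] = [tallies.get((m, b), 0) for m in motifs]
    return BinCountTable(
        genotype=genotype, counts=counts, ledger=dict(ledger), raw_total=raw
    )


def count_motifs_from_fastq(
    paths: Iterable[str | Path],
    template: AmpliconTemplate,
    barcode_map: dict[str, str] | None = None,
    genotype: str = "NA",
) -> BinCountTable:
    """As :func:`count_motifs`, pooling reads from one or more FASTQ files
    (the bin assignment comes from each read's barcode, not the file)."""

    def pooled() -> Iterator[str]:
        for path in paths:
            yield from iter_fastq_sequences(path)

    return count_motifs(pooled(), template, barcode_map, genotype=genotype)
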