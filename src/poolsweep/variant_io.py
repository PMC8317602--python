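"""Reading, filtering and QC of pool-seq allele-count tables.

The in-memory variant container is a :class:`pandas.DataFrame` with one row
per biallelic site and the columns

====== ======================================================
chrom  chromosome id (str)
pos    1-based position (int)
ref    reference allele string
alt    alternate allele string (``<DEL>`` for sync deletion evidence)
is_indel  True when ref/alt lengths differ (bool)
qual   Phred-like site quality (float; sync input carries none and
       receives :data:`SYNC_DEFAULT_QUAL`)
ref1, alt1  reads supporting ref/alt in pool 1
ref2, alt2  reads supporting ref/alt in pool 2
====== ======================================================

Pool 1 is the small (target) pool and pool 2 the large (reference) pool
throughout the package; per-pool depth is ``refN + altN``.

Two input dialects are supported: the Popoolation2 "sync" format
(tab-separated, per pool an ``A:T:C:G:N:del`` count sextet) and VCF with
per-sample allelic depths (``AD``).  Gene annotations come in as GFF3.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, OrderingError, ParseError

logger = logging.getLogger(__name__)

#: Column order of the variant table.
VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "is_indel", "qual",
    "ref1", "alt1", "ref2", "alt2",
]

#: Quality assigned to sync records (the format has no quality column).
SYNC_DEFAULT_QUAL = 255.0

_SYNC_BASES = ("A", "T", "C", "G")  # sextet order A:T:C:G:N:del

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


@dataclass(frozen=True)
class PoolSpec:
    """A sequenced pool of diploid individuals.

    ``n_haploid`` (= 2 x individuals) is the sample size n_i entering the
    Weir-Cockerham estimator.
    """

    n_individuals: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ConfigError("pool must contain at least one individual")

    @property
    def n_haploid(self) -> int:
        return 2 * self.n_individuals


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic site; mirrors a row of the variant table."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    ref1: int
    alt1: int
    ref2: int
    alt2: int

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt) or self.alt == "<DEL>"


def records_frame(records) -> pd.DataFrame:
    """Build a variant table from an iterable of :class:`VariantRecord`."""
    rows = [
        (r.chrom, r.pos, r.ref, r.alt, r.is_indel, r.qual,
         r.ref1, r.alt1, r.ref2, r.alt2)
        for r in records
    ]
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_sync(path, pool_specs, default_qual: float = SYNC_DEFAULT_QUAL) -> pd.DataFrame:
    """Read a Popoolation2 sync file into the variant table.

    The most frequent non-reference base (counts summed over pools) becomes
    the alternate allele; ties break in A,T,C,G order.  A record whose
    pooled ``del`` count exceeds every non-reference base count is typed as
    an indel with alt ``<DEL>`` and the del counts as alt support.
    """
    n_pools = len(pool_specs)
    if n_pools != 2:
        raise ConfigError("exactly two pools are supported")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3 + n_pools:
                raise ParseError(
                    f"{path}:{lineno}: expected {3 + n_pools} columns, got {len(fields)}"
                )
            chrom, pos_s, ref = fields[:3]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad position {pos_s!r}") from exc
            counts = []
            for sextet in fields[3:]:
                parts = sextet.split(":")
                if len(parts) != 6:
                    raise ParseError(
                        f"{path}:{lineno}: malformed count sextet {sextet!r}"
                    )
                try:
                    counts.append([int(x) for x in parts])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric count in {sextet!r}"
                    ) from exc
            ref = ref.upper()
            base_totals = {
                b: sum(c[i] for c in counts)
                for i, b in enumerate(_SYNC_BASES) if b != ref
            }
            del_total = sum(c[5] for c in counts)
            best_base = max(base_totals, key=lambda b: (base_totals[b], -_SYNC_BASES.index(b)))
            if del_total > base_totals[best_base]:
                alt = "<DEL>"
                alt_idx = 5
            else:
                alt = best_base
                alt_idx = _SYNC_BASES.index(best_base)
            ref_idx = _SYNC_BASES.index(ref) if ref in _SYNC_BASES else None
            per_pool = []
            for c in counts:
                rc = c[ref_idx] if ref_idx is not None else 0
                per_pool.extend((rc, c[alt_idx]))
            rows.append((chrom, pos, ref, alt, alt == "<DEL>",
                         float(default_qual), *per_pool))
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def write_sync(records: pd.DataFrame, path) -> None:
    """Write the variant table as a two-pool sync file.

    SNP counts go to the base slots; indel alt support goes to the ``del``
    slot (sync cannot represent the inserted/deleted sequence itself).
    """
    base_slot = {b: i for i, b in enumerate(_SYNC_BASES)}
    with open(path, "w") as fh:
        for row in records.itertuples(index=False):
            ref_base = row.ref[0]  # sync holds the single reference base
            pools = ((row.ref1, row.alt1), (row.ref2, row.alt2))
            sextets = []
            for rc, ac in pools:
                c = [0, 0, 0, 0, 0, 0]
                if ref_base in base_slot:
                    c[base_slot[ref_base]] = int(rc)
                if row.is_indel or row.alt not in base_slot:
                    c[5] = int(ac)
                else:
                    c[base_slot[row.alt]] = int(ac)
                sextets.append(":".join(str(x) for x in c))
            fh.write(f"{row.chrom}\t{row.pos}\t{ref_base}\t" + "\t".join(sextets) + "\n")


def read_vcf_counts(path, multiallelic: str = "two_most_frequent") -> pd.DataFrame:
    """Read a two-sample VCF with per-sample allelic depths (AD).

    Sample order in the VCF defines pool order.  Multiallelic sites keep
    the two best-supported alleles (``multiallelic='two_most_frequent'``,
    flagged via a warning) or are dropped (``'skip'``).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if len(vcf.samples) != 2:
        raise FormatError(
            f"{path}: expected 2 pool samples, found {len(vcf.samples)}"
        )
    rows = []
    n_multi = 0
    for v in vcf:
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise FormatError(f"{path}: record {v.CHROM}:{v.POS} lacks the AD field")
        ad = np.asarray(ad, dtype=float)
        ad[ad < 0] = 0  # missing markers
        alleles = [v.REF] + list(v.ALT)
        if len(alleles) < 2:
            continue
        if len(alleles) > 2:
            n_multi += 1
            if multiallelic == "skip":
                continue
            order = np.argsort(-ad.sum(axis=0))
            top = sorted(order[:2])  # prefer REF as ref when it survives
            ref_i, alt_i = int(top[0]), int(top[1])
        else:
            ref_i, alt_i = 0, 1
        ref, alt = alleles[ref_i], alleles[alt_i]
        qual = float(v.QUAL) if v.QUAL is not None else float("nan")
        rows.append((
            v.CHROM, v.POS, ref, alt, len(ref) != len(alt), qual,
            int(ad[0, ref_i]), int(ad[0, alt_i]),
            int(ad[1, ref_i]), int(ad[1, alt_i]),
        ))
    if n_multi and multiallelic == "two_most_frequent":
        warnings.warn(
            f"{n_multi} multiallelic site(s) reduced to their two best-supported alleles"
        )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def write_vcf(records: pd.DataFrame, path, contig_lengths=None,
              sample_names=("pool1", "pool2")) -> None:
    """Write the variant table as a minimal VCF 4.2 with AD/DP per pool."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
                 '"Allelic depths for the ref and alt alleles">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        for row in records.itertuples(index=False):
            s1 = f"{row.ref1},{row.alt1}:{row.ref1 + row.alt1}"
            s2 = f"{row.ref2},{row.alt2}:{row.ref2 + row.alt2}"
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t"
                     f"{row.qual:.1f}\t.\t.\tAD:DP\t{s1}\t{s2}\n")


def read_gff3(path) -> pd.DataFrame:
    """Extract gene features from a GFF3 file.

    Returns a frame with columns id, symbol, chrom, start, end, strand;
    coordinates stay 1-based inclusive.  Genes without a Name attribute
    keep their stable id as the symbol.  A file with no gene features
    yields an empty frame and a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for g in db.features_of_type("gene"):
        symbol = (g.attributes.get("Name") or g.attributes.get("gene_name")
                  or [g.id])[0]
        rows.append((g.id, symbol, g.seqid, g.start, g.end, g.strand))
    if not rows:
        warnings.warn(f"{path}: no gene features found")
    return pd.DataFrame(
        rows, columns=["id", "symbol", "chrom", "start", "end", "strand"]
    )


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    """SNP quality thresholds.

    A SNP is discarded when its pooled minor-allele frequency falls below
    ``min_maf`` (strict), any pool's depth falls below ``min_depth``
    (``depth_mode='per_pool'``; ``'combined'`` sums both pools), quality
    falls below ``min_qual``, or it lies within ``indel_dist`` bp
    (inclusive) of an indel on the same chromosome.
    """

    min_maf: float = 0.05
    min_depth: int = 10
    min_qual: float = 20.0
    indel_dist: int = 15
    depth_mode: str = "per_pool"

    def __post_init__(self) -> None:
        if not 0 <= self.min_maf < 0.5:
            raise ConfigError("min_maf must lie in [0, 0.5)")
        if self.min_depth < 0 or self.min_qual < 0 or self.indel_dist < 0:
            raise ConfigError("thresholds must be non-negative")
        if self.depth_mode not in ("per_pool", "combined"):
            raise ConfigError("depth_mode must be 'per_pool' or 'combined'")


@dataclass
class FilterReport:
    """Accounting of one filtering pass.

    ``by_rule`` tallies every rule a record violated (a record failing two
    rules counts once per rule); ``discarded`` counts each record once, so
    ``retained + discarded == n_input`` always.
    """

    n_input: int = 0
    retained: int = 0
    discarded: int = 0
    by_rule: dict = field(default_factory=dict)

    def balances(self) -> bool:
        return self.retained + self.discarded == self.n_input

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input), ("retained", self.retained),
                ("discarded", self.discarded)]
        rows += [(f"rule:{k}", v) for k, v in self.by_rule.items()]
        return pd.DataFrame(rows, columns=["category", "count"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _check_sorted(records: pd.DataFrame) -> None:
    chrom = records["chrom"].to_numpy()
    pos = records["pos"].to_numpy()
    new_chrom = np.r_[True, chrom[1:] != chrom[:-1]]
    if np.any(~new_chrom[1:] & (np.diff(pos) < 0)):
        raise OrderingError("records must be sorted by (chromosome, position)")
    # chromosomes must form contiguous blocks
    seen = {}
    for c in chrom[new_chrom]:
        if c in seen:
            raise OrderingError(f"chromosome {c} appears in non-contiguous blocks")
        seen[c] = True


def apply_filters(records: pd.DataFrame, config: FilterConfig | None = None):
    """Apply the SNP quality rules; returns (retained SNPs, FilterReport).

    Indel records never enter the SNP output but serve as exclusion
    anchors for the proximity rule.  Input must be coordinate-sorted.
    """
    if config is None:
        config = FilterConfig()
    if records.empty:
        return records.copy(), FilterReport(0, 0, 0, {})
    _check_sorted(records)

    is_indel = records["is_indel"].to_numpy(bool)
    ref1 = records["ref1"].to_numpy(float)
    alt1 = records["alt1"].to_numpy(float)
    ref2 = records["ref2"].to_numpy(float)
    alt2 = records["alt2"].to_numpy(float)
    qual = records["qual"].to_numpy(float)

    ref_total = ref1 + ref2
    alt_total = alt1 + alt2
    total = ref_total + alt_total
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.minimum(ref_total, alt_total) / np.where(total > 0, total, np.nan)
    fail_maf = ~(maf >= config.min_maf)  # NaN (zero-depth) fails too

    if config.depth_mode == "per_pool":
        fail_depth = ((ref1 + alt1) < config.min_depth) | ((ref2 + alt2) < config.min_depth)
    else:
        fail_depth = total < config.min_depth
    fail_qual = qual < config.min_qual

    # distance to the nearest indel on the same chromosome
    fail_indel = np.zeros(len(records), dtype=bool)
    pos = records["pos"].to_numpy()
    chrom = records["chrom"].to_numpy()
    for c in pd.unique(chrom):
        sel = chrom == c
        anchors = np.sort(pos[sel & is_indel])
        if anchors.size == 0:
            continue
        p = pos[sel]
        idx = np.searchsorted(anchors, p)
        left = np.where(idx > 0, p - anchors[np.maximum(idx - 1, 0)], np.iinfo(np.int64).max)
        right = np.where(idx < anchors.size,
                         anchors[np.minimum(idx, anchors.size - 1)] - p,
                         np.iinfo(np.int64).max)
        fail_indel[sel] = np.minimum(left, right) <= config.indel_dist

    snp = ~is_indel
    by_rule = {
        "maf": int(np.sum(snp & fail_maf)),
        "depth": int(np.sum(snp & fail_depth)),
        "qual": int(np.sum(snp & fail_qual)),
        "near_indel": int(np.sum(snp & fail_indel)),
        "indel_record": int(np.sum(is_indel)),
    }
    keep = snp & ~(fail_maf | fail_depth | fail_qual | fail_indel)
    report = FilterReport(
        n_input=len(records),
        retained=int(keep.sum()),
        discarded=int((~keep).sum()),
        by_rule=by_rule,
    )
    logger.info(
        "filtered %d records: %d retained, %d discarded %s",
        report.n_input, report.retained, report.discarded, by_rule,
    )
    return records.loc[keep].reset_index(drop=True), report


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def compute_tstv(records: pd.DataFrame):
    """Transition/transversion ratio of a SNP table.

    Returns ``(n_ts, n_tv, ratio)``; the ratio is NaN (undefined) when the
    transversion count is zero, including on empty input.
    """
    snps = records.loc[~records["is_indel"].to_numpy(bool)]
    ref = snps["ref"].to_numpy()
    alt = snps["alt"].to_numpy()
    valid = np.isin(ref, list("ACGT")) & np.isin(alt, list("ACGT")) & (ref != alt)
    ref, alt = ref[valid], alt[valid]
    purine_ref = np.isin(ref, list(_PURINES))
    purine_alt = np.isin(alt, list(_PURINES))
    ts = int(np.sum(purine_ref == purine_alt))
    tv = int(np.sum(purine_ref != purine_alt))
    if tv == 0:
        warnings.warn("Ts/Tv undefined: no transversions observed")
        return ts, tv, float("nan")
    return ts, tv, ts / tv
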