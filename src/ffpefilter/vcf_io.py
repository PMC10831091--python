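"""Read/write MuTect2-dialect VCF and insert-length QC from alignments.

All VCF traffic goes through :mod:`pysam`.  Reading splits multi-allelic
records into one :class:`VariantCall` per alt allele, taking each allele's
own slot of the Number=A/R annotations.  Coordinates stay VCF-native
(1-based, closed); no normalisation is applied because matched FF/FFPE
pairs are assumed to come from the identical calling pipeline, so allele
representations already agree.
"""

from __future__ import annotations

import os
import statistics
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import pysam

from .variants import VariantCall, VariantKey

ARTIFACT_FILTER = "ffpe_artifact"
PROB_INFO_KEY = "TVP"

#: MuTect2 FORMAT/INFO keys honored by the reader and writer.
_INFO_R_FLOAT = ("MBQ", "MMQ", "MFRL")
_INFO_A_FLOAT = ("MPOS", "TLOD", "POPAF")
_INFO_SITE_FLOAT = ("GERMQ", "SEQQ", "STRANDQ", "ROQ")


class VcfParseError(ValueError):
    """A record could not be interpreted as MuTect2-dialect output."""


@dataclass
class InsertLengthSummary:
    """Exact insert-length distribution from filtered, properly-paired reads."""

    lengths: List[int] = field(default_factory=list)
    n_reads_used: int = 0
    n_reads_excluded: int = 0

    @property
    def median(self) -> Optional[float]:
        """Order-statistic median; None when no read qualified."""
        if not self.lengths:
            return None
        return statistics.median(self.lengths)


def _allele_slot(values, idx: int):
    """Pick one allele's slot from a Number=A/R tuple; None-safe."""
    if values is None:
        return None
    if not isinstance(values, (tuple, list)):
        values = (values,)
    if idx >= len(values):
        return None
    v = values[idx]
    return None if v is None else v


def _select_sample(vf: pysam.VariantFile, sample: Optional[str]) -> Optional[str]:
    names = list(vf.header.samples)
    if sample is not None:
        if sample not in names:
            raise VcfParseError(f"sample {sample!r} not in VCF (has {names})")
        return sample
    if len(names) == 1:
        return names[0]
    if not names:
        return None
    raise VcfParseError(f"multi-sample VCF requires an explicit sample name (has {names})")


def read_mutect_vcf(
    path: str,
    pass_only: bool = False,
    sample: Optional[str] = None,
    strict: bool = False,
) -> List[VariantCall]:
    """Parse a MuTect2-dialect VCF into per-allele :class:`VariantCall` objects.

    Parameters
    ----------
    path : str
        VCF file (plain or bgzipped).
    pass_only : bool
        Keep only records whose FILTER is PASS or unfiltered ('.').
    sample : str, optional
        Sample column to read FORMAT fields from.  Required for
        multi-sample (tumor/normal) files; the single sample is used
        otherwise.
    strict : bool
        Raise :class:`VcfParseError` when a record lacks AD or DP instead
        of recording a missing sentinel.
    """
    calls: List[VariantCall] = []
    with pysam.VariantFile(path) as vf:
        sname = _select_sample(vf, sample)
        for rec in vf:
            filters = frozenset(rec.filter.keys())
            if pass_only and not filters <= {"PASS", "."}:
                continue
            fmt = rec.samples[sname] if sname is not None else {}
            try:
                calls.extend(_split_record(rec, fmt, filters, strict))
            except VcfParseError:
                raise
            except (ValueError, TypeError) as exc:  # non-numeric annotation etc.
                raise VcfParseError(f"bad annotation at {rec.chrom}:{rec.pos}: {exc}") from exc
    return calls


def _split_record(rec, fmt, filters, strict) -> List[VariantCall]:
    ad = fmt.get("AD") if fmt is not None else None
    dp = fmt.get("DP") if fmt is not None else None
    if dp is None:
        dp = rec.info.get("DP")
    if strict and (ad is None or dp is None):
        raise VcfParseError(f"record {rec.chrom}:{rec.pos} missing required AD/DP")
    f1r2 = fmt.get("F1R2") if fmt is not None else None
    f2r1 = fmt.get("F2R1") if fmt is not None else None

    info_r = {k: rec.info.get(k) for k in _INFO_R_FLOAT}
    info_a = {k: rec.info.get(k) for k in _INFO_A_FLOAT}
    site = {k: rec.info.get(k) for k in _INFO_SITE_FLOAT}
    ecnt = rec.info.get("ECNT")

    out = []
    alts = rec.alts or ()
    for i, alt in enumerate(alts):
        if alt is None or set(alt.upper()) - set("ACGT"):
            continue  # symbolic/spanning alleles are not classifiable calls
        ai = i + 1  # slot in Number=R vectors
        key = VariantKey(rec.chrom, rec.pos, rec.ref.upper(), alt.upper())
        sf = lambda v: None if v is None else float(v)
        out.append(
            VariantCall(
                key=key,
                depth=None if dp is None else int(dp),
                ad_ref=None if _allele_slot(ad, 0) is None else int(_allele_slot(ad, 0)),
                ad_alt=None if _allele_slot(ad, ai) is None else int(_allele_slot(ad, ai)),
                f1r2_ref=None if _allele_slot(f1r2, 0) is None else int(_allele_slot(f1r2, 0)),
                f1r2_alt=None if _allele_slot(f1r2, ai) is None else int(_allele_slot(f1r2, ai)),
                f2r1_ref=None if _allele_slot(f2r1, 0) is None else int(_allele_slot(f2r1, 0)),
                f2r1_alt=None if _allele_slot(f2r1, ai) is None else int(_allele_slot(f2r1, ai)),
                mbq_ref=sf(_allele_slot(info_r["MBQ"], 0)),
                mbq_alt=sf(_allele_slot(info_r["MBQ"], ai)),
                mmq_ref=sf(_allele_slot(info_r["MMQ"], 0)),
                mmq_alt=sf(_allele_slot(info_r["MMQ"], ai)),
                mfrl_ref=sf(_allele_slot(info_r["MFRL"], 0)),
                mfrl_alt=sf(_allele_slot(info_r["MFRL"], ai)),
                mpos=sf(_allele_slot(info_a["MPOS"], i)),
                tlod=sf(_allele_slot(info_a["TLOD"], i)),
                popaf=sf(_allele_slot(info_a["POPAF"], i)),
                ecnt=None if ecnt is None else int(ecnt),
                germq=sf(site["GERMQ"]),
                seqq=sf(site["SEQQ"]),
                strandq=sf(site["STRANDQ"]),
                roq=sf(site["ROQ"]),
                filter_status=filters,
            )
        )
    return out


def build_mutect_header(
    contigs: Dict[str, int],
    sample: str = "TUMOR",
    extra_filters: Sequence[str] = (),
    with_probability: bool = False,
) -> pysam.VariantHeader:
    """Construct a MuTect2-dialect VCF header for the writer."""
    h = pysam.VariantHeader()
    for name, length in contigs.items():
        h.contigs.add(name, length=length)
    h.filters.add("weak_evidence", None, None, "Mutation does not meet likelihood threshold")
    for f in extra_filters:
        if f not in ("PASS", ".") and f not in h.filters:
            h.filters.add(f, None, None, "Caller-assigned filter")
    if with_probability:
        h.filters.add(ARTIFACT_FILTER, None, None, "Classified as FFPE-induced artifact")
        h.info.add(PROB_INFO_KEY, 1, "Float", "Probability of being a true variant")
    h.info.add("ECNT", 1, "Integer", "Number of events in this haplotype")
    for k, desc in (
        ("MBQ", "median base quality by allele"),
        ("MMQ", "median mapping quality by allele"),
        ("MFRL", "median fragment length by allele"),
    ):
        h.info.add(k, "R", "Float", desc)
    for k, desc in (
        ("MPOS", "median distance from end of read"),
        ("TLOD", "Log odds of variant existing versus artifact"),
        ("POPAF", "negative log10 population allele frequency"),
    ):
        h.info.add(k, "A", "Float", desc)
    for k, desc in (
        ("GERMQ", "Phred-scaled quality that alleles are not germline"),
        ("SEQQ", "Phred-scaled quality that alleles are not sequencing errors"),
        ("STRANDQ", "Phred-scaled quality of strand bias artifact"),
        ("ROQ", "Phred-scaled quality that alleles are not read-orientation artifacts"),
    ):
        h.info.add(k, 1, "Float", desc)
    h.formats.add("GT", 1, "String", "Genotype")
    h.formats.add("AD", "R", "Integer", "Allelic depths")
    h.formats.add("AF", "A", "Float", "Allele fraction")
    h.formats.add("DP", 1, "Integer", "Approximate read depth")
    h.formats.add("F1R2", "R", "Integer", "Count of reads in F1R2 pair orientation")
    h.formats.add("F2R1", "R", "Integer", "Count of reads in F2R1 pair orientation")
    h.add_sample(sample)
    return h


def _contigs_from_calls(calls: Sequence[VariantCall]) -> Dict[str, int]:
    contigs: Dict[str, int] = {}
    for c in calls:
        contigs[c.key.chrom] = max(contigs.get(c.key.chrom, 0), c.key.pos + len(c.key.ref) + 1000)
    return contigs


def write_mutect_vcf(
    calls: Sequence[VariantCall],
    path: str,
    sample: str = "TUMOR",
    probabilities: Optional[Sequence[float]] = None,
    threshold: float = 0.5,
    contigs: Optional[Dict[str, int]] = None,
) -> None:
    """Write calls as a bi-allelic MuTect2-dialect VCF (one record per call).

    When ``probabilities`` is given, each record gains an INFO field with
    the true-variant probability (3 decimals) and calls with probability
    strictly below ``threshold`` receive the ``ffpe_artifact`` FILTER.
    """
    if probabilities is not None:
        if len(probabilities) != len(calls):
            raise ValueError(f"{len(calls)} calls but {len(probabilities)} probabilities")
        for p in probabilities:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
    extra = sorted({f for c in calls for f in c.filter_status})
    header = build_mutect_header(
        contigs or _contigs_from_calls(calls),
        sample=sample,
        extra_filters=extra,
        with_probability=probabilities is not None,
    )
    tmp = path + ".tmp"
    with pysam.VariantFile(tmp, "w", header=header) as out:
        for i, c in enumerate(calls):
            rec = out.new_record(
                contig=c.key.chrom,
                start=c.key.pos - 1,
                stop=c.key.pos - 1 + len(c.key.ref),
                alleles=(c.key.ref, c.key.alt),
            )
            labels = set(c.filter_status) - {"PASS", "."}
            if probabilities is not None:
                p = round(float(probabilities[i]), 3)
                rec.info[PROB_INFO_KEY] = p
                if p < threshold:
                    labels.add(ARTIFACT_FILTER)
            if labels:
                for f in sorted(labels):
                    rec.filter.add(f)
            else:
                rec.filter.add("PASS")
            _set_pair = lambda k, a, b: None if a is None or b is None else rec.info.__setitem__(k, (a, b))
            _set_pair("MBQ", c.mbq_ref, c.mbq_alt)
            _set_pair("MMQ", c.mmq_ref, c.mmq_alt)
            _set_pair("MFRL", c.mfrl_ref, c.mfrl_alt)
            for k, v in (
                ("MPOS", c.mpos),
                ("TLOD", c.tlod),
                ("POPAF", c.popaf),
            ):
                if v is not None:
                    rec.info[k] = (float(v),)
            for k, v in (
                ("ECNT", c.ecnt),
                ("GERMQ", c.germq),
                ("SEQQ", c.seqq),
                ("STRANDQ", c.strandq),
                ("ROQ", c.roq),
            ):
                if v is not None:
                    rec.info[k] = v
            smp = rec.samples[sample]
            smp["GT"] = (0, 1)
            if c.ad_ref is not None and c.ad_alt is not None:
                smp["AD"] = (c.ad_ref, c.ad_alt)
                denom = c.ad_ref + c.ad_alt
                if denom > 0:
                    smp["AF"] = (round(c.ad_alt / denom, 4),)
            if c.depth is not None:
                smp["DP"] = c.depth
            if c.f1r2_ref is not None and c.f1r2_alt is not None:
                smp["F1R2"] = (c.f1r2_ref, c.f1r2_alt)
            if c.f2r1_ref is not None and c.f2r1_alt is not None:
                smp["F2R1"] = (c.f2r1_ref, c.f2r1_alt)
            out.write(rec)
    os.replace(tmp, path)


def write_classified_vcf(
    calls: Sequence[VariantCall],
    probabilities: Sequence[float],
    threshold: float,
    path: str,
    sample: str = "TUMOR",
) -> None:
    """Write calls with true-variant probabilities and artifact FILTER labels."""
    write_mutect_vcf(calls, path, sample=sample, probabilities=probabilities, threshold=threshold)


def compute_insert_lengths(alignments: Iterable) -> InsertLengthSummary:
    """Summarise insert lengths over reads passing the five QC criteria.

    A read contributes only if it is properly paired, not a duplicate, not
    secondary, not supplementary, and has mapping quality strictly greater
    than 20.  Each template is counted once, via the mate with positive
    template length.
    """
    summary = InsertLengthSummary()
    for read in alignments:
        ok = (
            read.is_proper_pair
            and not read.is_duplicate
            and not read.is_secondary
            and not read.is_supplementary
            and read.mapping_quality > 20
        )
        # positive-TLEN mate carries the insert once per template
        if ok and read.template_length > 0:
            summary.n_reads_used += 1
            summary.lengths.append(int(read.template_length))
        else:
            summary.n_reads_excluded += 1
    return summary


def insert_lengths_from_bam(path: str, region: Optional[str] = None) -> InsertLengthSummary:
    """Convenience wrapper applying :func:`compute_insert_lengths` to a BAM/SAM file."""
    with pysam.AlignmentFile(path) as bam:
        it = bam.fetch(region=region) if region else bam
        return compute_insert_lengths(it)
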