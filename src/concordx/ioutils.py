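"""Standard-format I/O: FASTA, SAM, VCF, BED, TSV and the YAML simulation config.

Conventions, preserved losslessly for the fields this pipeline uses:
VCF and the truth table are 1-based; BED and everything internal are 0-based
half-open. SAM carries the strand in FLAG 0x10, duplicate marking in FLAG
0x400, the run id in the RG tag and simulation truth provenance in the XO tag.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta

from . import simulate as sim
from .caller import VariantCall
from .genotypes import RunEvidence, SiteEvidence
from .mismap import DupInterval, DuplicationAnnotation
from .reads import AlignedRead, ReadOrigin, Reference

PathLike = Union[str, Path]

DEFAULT_X_NAMES = ("chrX", "X")


# ---------------------------------------------------------------- FASTA

def write_fasta(reference: Reference, path: PathLike) -> None:
    records = [
        SeqRecord(Seq(reference.seq(name)), id=name, description="") for name in reference.names
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: PathLike, x_chroms: Iterable[str] = DEFAULT_X_NAMES) -> Reference:
    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
    return Reference.from_strings(seqs, x_chroms=[n for n in seqs if n in set(x_chroms)])


# ---------------------------------------------------------------- SAM

_FLAG_REVERSE = 0x10
_FLAG_DUP = 0x400


def write_sam(reads: Sequence[AlignedRead], reference: Reference, path: PathLike) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": reference.lengths[name]} for name in reference.names],
        "RG": [{"ID": run_id} for run_id in sorted({r.run_id for r in reads})] or [{"ID": "run"}],
    }
    tid = {name: i for i, name in enumerate(reference.names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(sam.header)
            a.query_name = f"read{i:08d}"
            a.query_sequence = r.sequence
            a.flag = (_FLAG_REVERSE if r.strand == "-" else 0) | (_FLAG_DUP if r.duplicate_flag else 0)
            a.reference_id = tid[r.chrom]
            a.reference_start = r.start
            a.mapping_quality = r.mapq
            a.cigartuples = [(0, len(r.sequence))]
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.base_qualities)
            )
            a.set_tag("RG", r.run_id)
            if r.truth_origin is not None:
                a.set_tag("XO", r.truth_origin.to_tag())
            sam.write(a)


def read_sam(path: PathLike) -> list[AlignedRead]:
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for a in sam:
            if a.is_unmapped:
                continue
            origin = ReadOrigin.from_tag(a.get_tag("XO")) if a.has_tag("XO") else None
            run_id = a.get_tag("RG") if a.has_tag("RG") else "run"
            reads.append(
                AlignedRead(
                    run_id=str(run_id),
                    chrom=a.reference_name,
                    start=a.reference_start,
                    strand="-" if a.is_reverse else "+",
                    mapq=a.mapping_quality,
                    sequence=a.query_sequence,
                    base_qualities=np.asarray(a.query_qualities, dtype=np.uint8),
                    duplicate_flag=a.is_duplicate,
                    truth_origin=origin,
                )
            )
    return reads


# ---------------------------------------------------------------- VCF

def _vcf_header(reference: Reference) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name in reference.names:
        header.contigs.add(name, length=reference.lengths[name])
    header.info.add("RR", 1, "Integer", "Reference-supporting filtered reads")
    header.info.add("VR", 1, "Integer", "Variant-supporting filtered reads")
    header.info.add("TR", 1, "Integer", "Total filtered reads at the site")
    header.info.add("VF", 1, "Float", "Variant fraction VR/(RR+VR)")
    header.info.add("TIER", 1, "String", "Confidence tier: candidate or high_confidence")
    header.info.add("GT_LABEL", 1, "String", "Genotype from the variant-fraction band")
    header.info.add("FLAGS", ".", "String", "Quality flags (STRAND_BIAS, LOW_MAPQ_SUPPORT)")
    return header


def write_vcf(calls: Sequence[VariantCall], reference: Reference, path: PathLike) -> None:
    header = _vcf_header(reference)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in calls:
            rec = vcf.new_record(
                contig=c.chrom, start=c.pos - 1, alleles=(c.ref, c.alt), filter="PASS"
            )
            rec.info["RR"] = c.rr
            rec.info["VR"] = c.vr
            rec.info["TR"] = c.tr
            rec.info["VF"] = c.vf
            rec.info["TIER"] = c.tier
            rec.info["GT_LABEL"] = c.genotype
            if c.flags:
                rec.info["FLAGS"] = tuple(sorted(c.flags))
            vcf.write(rec)


# ---------------------------------------------------------------- BED

def write_dup_bed(annotation: DuplicationAnnotation, path: PathLike) -> None:
    """BED of the duplication family; 4th column is percent identity."""
    rows = [
        (iv.chrom, iv.start, iv.end, f"{iv.identity:.2f}", iv.partner or ("source" if iv.is_source else "."))
        for iv in annotation.intervals
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_dup_bed(path: PathLike) -> DuplicationAnnotation:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "identity", "partner"],
        dtype={"chrom": str, "partner": str},
    )
    intervals = []
    for i, row in df.iterrows():
        try:
            intervals.append(
                DupInterval(
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    identity=float(row["identity"]),
                    partner=row["partner"] if isinstance(row["partner"], str) else "",
                    is_source=row["partner"] == "source",
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed BED line {i + 1}: {exc}") from exc
    return DuplicationAnnotation(intervals)


def write_targets_bed(targets: Sequence[tuple[str, int, int]], path: PathLike) -> None:
    pd.DataFrame(targets).to_csv(path, sep="\t", header=False, index=False)


def read_targets_bed(path: PathLike) -> list[tuple[str, int, int]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
                     names=["chrom", "start", "end"], dtype={"chrom": str})
    out = []
    for i, row in df.iterrows():
        try:
            start, end = int(row["start"]), int(row["end"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed BED line {i + 1}: {exc}") from exc
        if end <= start:
            raise ValueError(f"{path}: malformed BED line {i + 1}: empty interval")
        out.append((row["chrom"], start, end))
    return out


# ---------------------------------------------------------------- truth / evidence TSV

def write_truth(truth: pd.DataFrame, path: PathLike) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "source_chrom": str})


def write_evidence(sites: Sequence[SiteEvidence], path: PathLike) -> None:
    rows = [
        {
            "chrom": s.key[0], "pos": s.key[1], "ref": s.key[2], "alt": s.key[3],
            "run_id": r.run_id, "rr": r.rr, "vr": r.vr,
            "genotype": r.genotype or "", "tier": r.tier or "",
        }
        for s in sites
        for r in s.runs
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "run_id", "rr", "vr", "genotype", "tier"]).to_csv(
        path, sep="\t", index=False
    )


def read_evidence(path: PathLike) -> list[SiteEvidence]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    sites: dict[tuple, SiteEvidence] = {}
    for _, row in df.iterrows():
        key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        site = sites.setdefault(key, SiteEvidence(key=key))
        site.runs.append(
            RunEvidence(
                run_id=str(row["run_id"]),
                rr=int(row["rr"]),
                vr=int(row["vr"]),
                genotype=row["genotype"] or None,
                tier=row["tier"] or None,
            )
        )
    return list(sites.values())


# ---------------------------------------------------------------- YAML config

def config_to_dict(config: sim.SimulationConfig) -> dict:
    d = {
        "seed": config.seed,
        "sample_sex": config.sample_sex,
        "chromosomes": [dataclasses.asdict(c) for c in config.chromosomes],
        "dup_segment": None,
        "variants": [
            {k: v for k, v in dataclasses.asdict(v).items() if v is not None}
            for v in config.variant_specs
        ],
        "runs": [dataclasses.asdict(p) for p in config.run_profiles],
    }
    if config.dup_segment is not None:
        ds = dataclasses.asdict(config.dup_segment)
        if ds["copy_sites"] is not None:
            ds["copy_sites"] = [list(site) for site in ds["copy_sites"]]
        d["dup_segment"] = ds
    return d


def config_from_dict(d: dict) -> sim.SimulationConfig:
    dup = None
    if d.get("dup_segment"):
        ds = dict(d["dup_segment"])
        if ds.get("copy_sites"):
            ds["copy_sites"] = tuple((c, int(s)) for c, s in ds["copy_sites"])
        dup = sim.DupSegmentSpec(**ds)
    return sim.SimulationConfig(
        chromosomes=[sim.ChromosomeSpec(**c) for c in d["chromosomes"]],
        dup_segment=dup,
        sample_sex=d.get("sample_sex", "male"),
        variant_specs=[sim.PlantedVariant(**v) for v in d.get("variants", [])],
        run_profiles=[sim.RunProfile(**p) for p in d.get("runs", [])],
        seed=int(d.get("seed", 1)),
    )


def save_config(config: sim.SimulationConfig, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path: PathLike) -> sim.SimulationConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
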