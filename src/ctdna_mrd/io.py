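"""File-format plumbing: VCF, BED, TSV, JSON and SAM round-trips.

Conventions: VCF-facing loci are 1-based; interval sets (BED) are 0-based
half-open. Panels serialize as a directory of three files -- a BED of target
loci, a TSV manifest (one row per MRD target or QA SNV), and a JSON header
with design provenance.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from cyvcf2 import VCF

from .consensus import BOTTOM, TOP, AlignedReadPair, ConsensusMolecule
from .panel_design import (
    EXCLUSION_CATEGORIES,
    BespokePanel,
    GenomicExclusionSet,
    PanelTarget,
    QaSnv,
    SomaticVariantCall,
)

# ---------------------------------------------------------------------------
# VCF


def read_somatic_vcf(path, af_field: str = "AF",
                     require_pass: bool = True) -> list[SomaticVariantCall]:
    """Read somatic SNV calls; AF is taken from INFO or the first FORMAT sample."""
    calls = []
    for v in VCF(str(path)):
        if len(v.REF) != 1 or len(v.ALT) != 1 or len(v.ALT[0]) != 1:
            continue  # not an SNV
        passed = v.FILTER is None
        af = v.INFO.get(af_field)
        if af is None:
            fmt = v.format(af_field)
            if fmt is not None:
                af = float(np.asarray(fmt).ravel()[0])
        if af is None:
            raise ValueError(f"no {af_field} annotation at {v.CHROM}:{v.POS}")
        if require_pass and not passed:
            continue
        calls.append(
            SomaticVariantCall(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=v.ALT[0],
                tumor_af=float(af),
                tumor_depth=int(v.INFO.get("DP") or 0),
                passed_caller_filters=passed,
            )
        )
    return calls


def write_somatic_vcf(calls: Sequence[SomaticVariantCall], path,
                      contig_lengths: Mapping[str, int]) -> None:
    header = pysam.VariantHeader()
    for chrom in sorted(contig_lengths):
        header.contigs.add(chrom, length=contig_lengths[chrom])
    header.info.add("AF", "A", "Float", "Tumor allele frequency")
    header.info.add("DP", 1, "Integer", "Tumor read depth")
    header.filters.add("LowQual", None, None, "Failed somatic caller filters")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            rec = out.new_record(
                contig=c.chrom, start=c.pos - 1, stop=c.pos,
                alleles=(c.ref, c.alt),
            )
            rec.info["AF"] = c.tumor_af
            rec.info["DP"] = c.tumor_depth
            if not c.passed_caller_filters:
                rec.filter.add("LowQual")
            out.write(rec)


# ---------------------------------------------------------------------------
# BED / exclusion sets


def read_bed(path) -> list[tuple[str, int, int]]:
    intervals = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        intervals.append((fields[0], int(fields[1]), int(fields[2])))
    return intervals


def read_exclusion_bed(path) -> list[GenomicExclusionSet]:
    """A 4-column BED whose name column is the exclusion category."""
    by_cat: dict[str, list[tuple[str, int, int]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end, cat = line.split("\t")[:4]
        by_cat.setdefault(cat, []).append((chrom, int(start), int(end)))
    return [GenomicExclusionSet(category=c, intervals=tuple(ivs))
            for c, ivs in sorted(by_cat.items())]


def read_exclusion_dir(directory) -> list[GenomicExclusionSet]:
    """One ``<category>.bed`` file per exclusion category."""
    sets = []
    for bed in sorted(Path(directory).glob("*.bed")):
        category = bed.stem
        if category not in EXCLUSION_CATEGORIES:
            raise ValueError(f"unknown exclusion category file {bed.name}")
        sets.append(GenomicExclusionSet(category=category,
                                        intervals=tuple(read_bed(bed))))
    return sets


def write_exclusion_bed(sets: Sequence[GenomicExclusionSet], path) -> None:
    lines = []
    for s in sets:
        for chrom, start, end in s.intervals:
            lines.append(f"{chrom}\t{start}\t{end}\t{s.category}")
    Path(path).write_text("\n".join(sorted(lines)) + "\n")


# ---------------------------------------------------------------------------
# SNP catalog


def read_snp_catalog(path) -> list[QaSnv]:
    """TSV with chrom, pos, ref, alt, population_frequency, hwe_pass and any
    number of ``subpop_<name>`` frequency columns."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    subpop_cols = [c for c in df.columns if c.startswith("subpop_")]
    catalog = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        catalog.append(
            QaSnv(
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                ref=d["ref"],
                alt=d["alt"],
                population_frequency=float(d["population_frequency"]),
                hwe_pass=bool(d["hwe_pass"]),
                subpopulation_frequencies={
                    c[len("subpop_"):]: float(d[c]) for c in subpop_cols
                },
            )
        )
    return catalog


def write_snp_catalog(catalog: Sequence[QaSnv], path) -> None:
    subpops = sorted({p for s in catalog for p in s.subpopulation_frequencies})
    rows = []
    for s in catalog:
        row = {
            "chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt,
            "population_frequency": s.population_frequency,
            "hwe_pass": s.hwe_pass,
        }
        for p in subpops:
            row[f"subpop_{p}"] = s.subpopulation_frequencies.get(p, float("nan"))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# panel


def write_panel(panel: BespokePanel, directory, metadata: dict | None = None) -> None:
    """Serialize a panel as BED + TSV manifest + JSON header."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    bed_lines = [
        f"{t.chrom}\t{t.pos - 1}\t{t.pos}\t{t.target_id}" for t in panel.targets
    ]
    (directory / "targets.bed").write_text("\n".join(bed_lines) + "\n")

    rows = []
    for t in panel.targets:
        rows.append({
            "chrom": t.chrom, "pos": t.pos, "ref": t.ref, "alt": t.alt,
            "af": t.tumor_af, "error_rate": t.error_rate,
            "rank_score": t.rank_score, "active": t.active, "type": "mrd",
        })
    for s in panel.qa_snvs:
        rows.append({
            "chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt,
            "af": s.population_frequency, "error_rate": float("nan"),
            "rank_score": float("nan"), "active": True, "type": "qa",
        })
    pd.DataFrame(rows).to_csv(directory / "manifest.tsv", sep="\t", index=False)

    header = {
        "patient_id": panel.patient_id,
        "n_targets": len(panel.targets),
        "n_active_targets": len(panel.active_targets),
        "n_qa_snvs": len(panel.qa_snvs),
        "predicted_lod_ppm": panel.predicted_lod_ppm,
    }
    header.update(metadata or {})
    (directory / "header.json").write_text(json.dumps(header, indent=2,
                                                      sort_keys=True) + "\n")


def read_panel(directory) -> BespokePanel:
    directory = Path(directory)
    header = json.loads((directory / "header.json").read_text())
    df = pd.read_csv(directory / "manifest.tsv", sep="\t", dtype={"chrom": str})
    targets, qa = [], []
    for row in df.itertuples(index=False):
        if row.type == "mrd":
            targets.append(PanelTarget(
                chrom=str(row.chrom), pos=int(row.pos), ref=row.ref,
                alt=row.alt, tumor_af=float(row.af),
                error_rate=float(row.error_rate),
                rank_score=float(row.rank_score), active=bool(row.active),
            ))
        else:
            qa.append(QaSnv(chrom=str(row.chrom), pos=int(row.pos),
                            ref=row.ref, alt=row.alt,
                            population_frequency=float(row.af)))
    return BespokePanel(
        patient_id=header["patient_id"],
        targets=targets,
        qa_snvs=qa,
        predicted_lod_ppm=header.get("predicted_lod_ppm"),
    )


# ---------------------------------------------------------------------------
# consensus molecules


def write_molecules_tsv(molecules: Sequence[ConsensusMolecule], path) -> None:
    rows = [
        {
            "chrom": m.fragment_key[0],
            "start": m.fragment_key[1],
            "end": m.fragment_key[2],
            "sequence": m.sequence,
            "n_members": m.n_members,
            "n_top": m.strand_support[0],
            "n_bottom": m.strand_support[1],
        }
        for m in molecules
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "sequence",
                                "n_members", "n_top", "n_bottom"]).to_csv(
        path, sep="\t", index=False)


def read_molecules_tsv(path) -> list[ConsensusMolecule]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        ConsensusMolecule(
            fragment_key=(str(r.chrom), int(r.start), int(r.end)),
            sequence=r.sequence,
            n_members=int(r.n_members),
            strand_support=(int(r.n_top), int(r.n_bottom)),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# SAM


def write_plasma_sam(
    pairs: Sequence[AlignedReadPair],
    path,
    contig_lengths: Mapping[str, int],
    read_length: int = 150,
) -> None:
    """Write merged fragments back out as conventional paired-end SAM records.

    Each fragment becomes two mates: one anchored at the fragment start, one
    ending at the fragment end, overlapping in the middle when the fragment is
    shorter than twice the read length. Top-strand pairs have read1 forward;
    bottom-strand pairs have read1 reverse. Output is deterministic.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": contig_lengths[c]} for c in sorted(contig_lengths)],
    }
    tid = {c: i for i, c in enumerate(sorted(contig_lengths))}
    ordered = sorted(pairs, key=lambda p: (p.fragment_key, p.read_id))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for pair in ordered:
            chrom, start, end = pair.fragment_key
            frag_len = end - start
            rlen = min(read_length, frag_len)
            for which in (1, 2):
                a = pysam.AlignedSegment()
                a.query_name = pair.read_id
                a.reference_id = tid[chrom]
                a.next_reference_id = tid[chrom]
                a.is_paired = True
                a.is_proper_pair = True
                a.is_read1 = which == 1
                a.is_read2 = which == 2
                at_start = (which == 1) == (pair.strand_tag == TOP)
                if at_start:
                    a.reference_start = start
                    seq_slice = slice(0, rlen)
                    a.is_reverse = False
                else:
                    a.reference_start = end - rlen
                    seq_slice = slice(frag_len - rlen, frag_len)
                    a.is_reverse = True
                a.mate_is_reverse = not a.is_reverse
                a.next_reference_start = start if not at_start else end - rlen
                a.template_length = frag_len if not a.is_reverse else -frag_len
                a.query_sequence = pair.bases[seq_slice]
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in pair.quals[seq_slice])
                )
                a.cigarstring = f"{rlen}M"
                a.mapping_quality = 60
                out.write(a)


def read_plasma_sam(path) -> tuple[list[AlignedReadPair], dict[str, int]]:
    """Reconstruct merged fragments from a paired-end SAM/BAM.

    Mates are merged over the outer fragment span; in overlap the
    higher-quality base wins. Pairs with unmapped, inter-chromosomal, or
    indel-containing mates are skipped and counted.
    """
    skipped = {"unpaired": 0, "inter_chromosomal": 0, "indel": 0, "unmapped": 0}
    mates: dict[str, list[pysam.AlignedSegment]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for aln in af:
            if aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_unmapped or aln.mate_is_unmapped:
                skipped["unmapped"] += 1
                continue
            mates.setdefault(aln.query_name, []).append(aln)

    pairs: list[AlignedReadPair] = []
    for name in sorted(mates):
        group = mates[name]
        if len(group) != 2:
            skipped["unpaired"] += len(group)
            continue
        r1 = next((r for r in group if r.is_read1), None)
        r2 = next((r for r in group if r.is_read2), None)
        if r1 is None or r2 is None:
            skipped["unpaired"] += 2
            continue
        if r1.reference_name != r2.reference_name:
            skipped["inter_chromosomal"] += 2
            continue
        if any(op != 0 for r in (r1, r2) for op, _ in (r.cigartuples or [])):
            skipped["indel"] += 2
            continue
        start = min(r1.reference_start, r2.reference_start)
        end = max(r1.reference_end, r2.reference_end)
        length = end - start
        bases = np.full(length, ord("N"), dtype=np.uint8)
        quals = np.zeros(length, dtype=np.int16)
        for r in (r1, r2):
            seq = np.frombuffer(r.query_sequence.encode("ascii"), dtype=np.uint8)
            q = np.asarray(r.query_qualities, dtype=np.int16)
            off = r.reference_start - start
            better = q > quals[off:off + len(seq)]
            bases[off:off + len(seq)][better] = seq[better]
            quals[off:off + len(seq)][better] = q[better]
        strand = TOP if not r1.is_reverse else BOTTOM
        pairs.append(
            AlignedReadPair(
                fragment_key=(r1.reference_name, start, end),
                strand_tag=strand,
                bases=bases.tobytes().decode("ascii"),
                quals=quals,
                read_id=name,
            )
        )
    return pairs, skipped
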