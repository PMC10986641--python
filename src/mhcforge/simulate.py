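"""Synthetic MHC haplotype fixtures with machine-readable planted truth.

Every downstream operation is testable without downloads: the generator
plants genes with known exon structure, an allele database with known
pairwise distances and completeness, C4 cassettes with or without the
HERV-like insertion, SNP/INDEL/SV edits with a construction-truth CIGAR,
pileup columns with controlled allele fractions, and repeat intervals.

Default variant densities emulate the real MHC: ~2.7 SNPs/kbp, ~0.45
INDELs/kbp and a handful of SVs per haplotype. The fixtures are a single
contig with uniform random background sequence; they deliberately do not
model segmental duplications, repeat-mediated microhomology or sequencing
chimeras. One integer seed drives a single deterministic generator stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import AlignmentRecord, revcomp
from .annotation import GeneModel
from .c4 import C4Reference
from .polishing import PileupColumn
from .seq_io import AlleleRecord, RepeatFeature, SequenceRecord

BASES = np.frombuffer(b"ACGT", dtype="S1")

# codons that cannot introduce a premature stop (also avoids ATG re-use noise)
_SAFE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

DEFAULT_LOCI = ("A", "B", "C", "DRA", "DQA1", "DQB1", "DPA1", "DRB1")

# DRB1 first field planted for each class II structural group, plus the
# required DRB paralog locus (None for DR1/DR8).
DR_PLANS = {
    "DR1": ("01", None),
    "DR2": ("15", "DRB5"),
    "DR3": ("13", "DRB3"),
    "DR4": ("04", "DRB4"),
    "DR8": ("08", None),
}

_FIRST_FIELDS = {
    "A": "01",
    "B": "07",
    "C": "07",
    "DRA": "01",
    "DQA1": "01",
    "DQB1": "06",
    "DPA1": "01",
    "DRB3": "01",
    "DRB4": "01",
    "DRB5": "01",
}


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def random_coding(rng: np.random.Generator, n_codons: int) -> str:
    """Stop-free codon run of the given length."""
    idx = rng.integers(0, len(_SAFE_CODONS), size=n_codons)
    return "".join(_SAFE_CODONS[i] for i in idx)


@dataclass
class VariantPlan:
    n_snps: int = 540
    n_indels: int = 90
    indel_size_range: tuple[int, int] = (1, 20)
    sv_sizes: tuple[tuple[str, int], ...] = (("del", 1500), ("ins", 1200))
    min_separation: int = 60


@dataclass
class PileupPlan:
    depths: dict[str, int] = field(
        default_factory=lambda: {"nanopore": 20, "illumina": 30}
    )
    error_rate: float = 0.01
    # (position, majority base, fraction per technology)
    discordances: list[tuple[int, str, dict[str, float]]] = field(default_factory=list)


@dataclass
class FixtureSpec:
    seed: int = 0
    length: int = 200_000
    loci: tuple[str, ...] = DEFAULT_LOCI
    dr_plan: str = "DR3"
    n_alleles_per_locus: int = 4
    c4_plan: tuple[tuple[str, str], ...] = (("A", "L"), ("B", "L"))
    variant_plan: VariantPlan = field(default_factory=VariantPlan)
    n_repeats: int = 60
    herv_length: int = 6000

    @classmethod
    def small(cls, seed: int = 0, **overrides) -> "FixtureSpec":
        """Reduced desk-scale preset (60 kb, 3 loci) for many-seed sweeps.

        Variant densities per kbp match the default spec.
        """
        params = dict(
            seed=seed,
            length=60_000,
            loci=("A", "DRA", "DRB1"),
            variant_plan=VariantPlan(
                n_snps=160, n_indels=27, sv_sizes=(("del", 1500), ("ins", 1200))
            ),
            n_repeats=20,
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class TruthTable:
    chosen_alleles: dict[str, str]
    gene_exons: dict[str, list[tuple[int, int]]]
    gene_strands: dict[str, str]
    gene_intervals: dict[str, tuple[int, int]]
    n_snps: int
    n_indels: int
    n_svs: int
    snp_positions: list[int]
    c4_genotype: str
    c4_intervals: list[tuple[int, int]]
    dr_group: str
    class2_interval: tuple[int, int]
    repeat_fraction: float
    allele_distances: dict[str, int]  # allele name -> planted mutation count


@dataclass
class HaplotypeFixture:
    spec: FixtureSpec
    reference: SequenceRecord  # pre-variant ancestor (stands in for PGF)
    assembly: SequenceRecord  # haplotype carrying the planted variants
    alignment: AlignmentRecord  # assembly (query) onto reference, by construction
    allele_db: list[AlleleRecord]
    allele_fasta: str
    locus_msas: dict[str, str]
    gene_models: list[GeneModel]
    c4_reference: C4Reference
    repeats: list[RepeatFeature]
    truth: TruthTable


@dataclass
class _Locus:
    name: str
    model: GeneModel
    alleles: list[AlleleRecord]
    msa_text: str
    distances: dict[str, int]


def simulate_locus(
    rng: np.random.Generator,
    locus: str,
    first_field: str,
    n_alleles: int = 4,
    n_exons: int = 4,
    intron_length: int = 150,
    cds_codons: int = 160,
) -> _Locus:
    """One locus: a gene model plus an allele set with planted distances.

    Allele k carries k SNPs relative to allele 1 (placed inside introns so
    the planted gene stays translatable); the last allele is an incomplete
    truncation of allele 1 (unknown 5' region in the MSA).
    """
    cds = "ATG" + random_coding(rng, cds_codons - 2) + "TAA"
    cut_points = sorted(
        rng.choice(np.arange(3, len(cds) - 3), size=n_exons - 1, replace=False).tolist()
    )
    pieces = []
    prev = 0
    for cp in cut_points + [len(cds)]:
        pieces.append(cds[prev:cp])
        prev = cp
    exons = []
    seq_parts = []
    pos = 0
    intron_spans = []
    for i, piece in enumerate(pieces):
        exons.append((pos, pos + len(piece)))
        seq_parts.append(piece)
        pos += len(piece)
        if i < len(pieces) - 1:
            intron = random_sequence(rng, intron_length)
            intron_spans.append((pos, pos + intron_length))
            seq_parts.append(intron)
            pos += intron_length
    genomic = "".join(seq_parts)
    model = GeneModel(
        gene_name=f"HLA-{locus}",
        tier="allele-db",
        genomic_sequence=genomic,
        exons=exons,
        coding=True,
    )
    # allele set
    alleles = []
    distances = {}
    msa_rows = []
    intron_positions = np.concatenate(
        [np.arange(s, e) for s, e in intron_spans]
    )
    base_name = f"{locus}*{first_field}"
    for k in range(n_alleles - 1):
        name = f"{base_name}:{k + 1:02d}"
        if k == 0:
            seq = genomic
        else:
            positions = rng.choice(intron_positions, size=k, replace=False)
            chars = list(genomic)
            for p in positions:
                old = chars[p]
                chars[p] = rng.choice([b for b in "ACGT" if b != old])
            seq = "".join(chars)
        alleles.append(AlleleRecord(name, locus, seq, True, (0, len(genomic))))
        distances[name] = k
        msa_rows.append((name, seq))
    trunc = int(rng.integers(200, 400))
    trunc_name = f"{base_name}:90"
    trunc_seq = genomic[trunc:]
    alleles.append(
        AlleleRecord(trunc_name, locus, trunc_seq, False, (trunc, len(genomic)))
    )
    distances[trunc_name] = 0
    msa_rows.append((trunc_name, "*" * trunc + trunc_seq))
    msa_text = "".join(f">{n}\n{s}\n" for n, s in msa_rows)
    return _Locus(locus, model, alleles, msa_text, distances)


def make_c4_reference(
    rng: np.random.Generator,
    herv_length: int = 6000,
    n_exons: int = 26,
    exon_length: int = 72,
    intron_length: int = 120,
) -> tuple[C4Reference, tuple[int, int]]:
    """Scaled-down HERV-carrying C4A reference plus its exon-26 motif span.

    Exon lengths are multiples of 3 (frame 0 throughout); exon 26 encodes a
    peptide containing PCPVLD. Intron 9 is ``herv_length`` long and the HERV
    interval is that intron minus 30 bp flanks.
    """
    exons: dict[int, tuple[int, int]] = {}
    frames: dict[int, int] = {}
    parts = []
    pos = 0
    motif_span = (0, 0)
    for num in range(1, n_exons + 1):
        if num == 26:
            n_codons = exon_length // 3
            motif_codon = n_codons // 2
            pep_codons = random_coding(rng, motif_codon)
            motif = "CCTTGTCCTGTGCTGGAT"  # encodes PCPVLD
            tail = random_coding(rng, n_codons - motif_codon - 6)
            exon_seq = pep_codons + motif + tail
            motif_span = (pos + 3 * motif_codon, pos + 3 * motif_codon + 18)
        else:
            exon_seq = random_coding(rng, exon_length // 3)
        exons[num] = (pos, pos + len(exon_seq))
        frames[num] = 0
        parts.append(exon_seq)
        pos += len(exon_seq)
        if num < n_exons:
            ilen = herv_length if num == 9 else intron_length
            parts.append(random_sequence(rng, ilen))
            pos += ilen
    seq = "".join(parts)
    herv_interval = (exons[9][1] + 30, exons[10][0] - 30)
    ref = C4Reference(sequence=seq, exons=exons, frames=frames, herv_interval=herv_interval)
    return ref, motif_span


B_MOTIF_DNA = "CTGTCTCCTGTGATTCAT"  # encodes LSPVIH


def cassette_sequence(
    ref: C4Reference, motif_span: tuple[int, int], isotype: str, herv: str
) -> str:
    """Concrete cassette for one planted C4 copy.

    Isotype B swaps the exon-26 motif codons; a short (S) copy deletes the
    HERV interval.
    """
    seq = ref.sequence
    if isotype == "B":
        seq = seq[: motif_span[0]] + B_MOTIF_DNA + seq[motif_span[1] :]
    if herv == "S":
        lo, hi = ref.herv_interval
        seq = seq[:lo] + seq[hi:]
    return seq


def _plant_edits(
    rng: np.random.Generator,
    ancestor: str,
    allowed: list[tuple[int, int]],
    plan: VariantPlan,
) -> tuple[str, AlignmentRecord, dict]:
    """Apply the variant plan inside the allowed intervals.

    Returns the derived sequence, the construction-truth alignment of the
    derived sequence (query) onto the ancestor (reference), and per-class
    truth positions. Planted edits never overlap (enforced separation).
    """
    sizes: list[tuple[str, int]] = [("snp", 1)] * plan.n_snps
    lo, hi = plan.indel_size_range
    for _ in range(plan.n_indels):
        kind = "ins" if rng.random() < 0.5 else "del"
        size = int(rng.integers(lo, hi + 1))
        if size >= 1000:
            raise ValueError("indel plan sizes must stay below the SV floor")
        sizes.append((kind, size))
    sizes.extend(plan.sv_sizes)

    candidates = []
    for s, e in allowed:
        if e - s > 2 * plan.min_separation:
            candidates.append((s + plan.min_separation, e - plan.min_separation))
    total = sum(e - s for s, e in candidates)
    needed = sum(sz for k, sz in sizes if k == "del") + len(sizes) * plan.min_separation
    if total < needed:
        raise ValueError("not enough spacer sequence to plant the variant plan")

    # sample non-overlapping anchor positions with the required separation;
    # each edit reserves only its own footprint plus the separation margin
    positions: list[int] = []
    span_starts = np.array([s for s, _ in candidates])
    span_ends = np.array([e for _, e in candidates])
    span_lens = span_ends - span_starts
    cum = np.cumsum(span_lens)
    taken: list[tuple[int, int]] = []
    attempts = 0
    # place large-footprint edits first so fragmentation cannot strand them
    sizes.sort(key=lambda ks: -(ks[1] if ks[0] == "del" else 1))
    for kind, size in sizes:
        extent = (size if kind == "del" else 1) + plan.min_separation
        while True:
            attempts += 1
            if attempts > 500 * len(sizes):
                raise ValueError("failed to place planted variants without overlap")
            r = int(rng.integers(0, total))
            idx = int(np.searchsorted(cum, r, side="right"))
            pos = int(span_starts[idx] + (r - (cum[idx - 1] if idx else 0)))
            if pos + extent > span_ends[idx]:
                continue
            if all(
                pos + extent <= s or pos - plan.min_separation >= e for s, e in taken
            ):
                taken.append((pos, pos + extent))
                positions.append(pos)
                break
    order = np.argsort(positions)
    edits = [(positions[i], *sizes[i]) for i in order]

    derived_parts: list[str] = []
    cigar: list[tuple[int, str]] = []
    truth = {"snp": [], "indel": [], "sv": []}

    def push(n, op):
        if n <= 0:
            return
        if cigar and cigar[-1][1] == op:
            cigar[-1] = (cigar[-1][0] + n, op)
        else:
            cigar.append((n, op))

    cursor = 0
    for pos, kind, size in edits:
        push(pos - cursor, "=")
        derived_parts.append(ancestor[cursor:pos])
        if kind == "snp":
            old = ancestor[pos]
            new = str(rng.choice([b for b in "ACGT" if b != old]))
            derived_parts.append(new)
            push(1, "X")
            truth["snp"].append(pos)
            cursor = pos + 1
        elif kind == "del":
            push(size, "D")
            (truth["sv"] if size >= 1000 else truth["indel"]).append(pos)
            cursor = pos + size
        else:  # ins
            derived_parts.append(random_sequence(rng, size))
            push(size, "I")
            (truth["sv"] if size >= 1000 else truth["indel"]).append(pos)
            cursor = pos
    push(len(ancestor) - cursor, "=")
    derived_parts.append(ancestor[cursor:])
    derived = "".join(derived_parts)
    n_matches = sum(n for n, op in cigar if op == "=")
    record = AlignmentRecord(
        query_id="assembly",
        target_id="reference",
        q_start=0,
        q_end=len(derived),
        t_start=0,
        t_end=len(ancestor),
        strand="+",
        cigar=cigar,
        n_matches=n_matches,
        block_length=sum(n for n, op in cigar),
        q_len=len(derived),
        t_len=len(ancestor),
    )
    return derived, record, truth


def _lift_factory(cigar: list[tuple[int, str]]):
    """Map ancestor (target) coordinates to derived (query) coordinates.

    Only valid for positions outside deleted ancestor segments, which holds
    for all planted features because edits are confined to spacers.
    """
    anc_starts: list[int] = []
    deltas: list[int] = []
    anc = der = 0
    for length, op in cigar:
        if op in "=X":
            anc_starts.append(anc)
            deltas.append(der - anc)
            anc += length
            der += length
        elif op == "I":
            der += length
        elif op == "D":
            anc += length
    starts = np.array(anc_starts)
    delta_arr = np.array(deltas)
    anc_end, der_end = anc, der

    def lift(pos: int) -> int:
        if pos >= anc_end:
            return pos - anc_end + der_end
        idx = int(np.searchsorted(starts, pos, side="right")) - 1
        return pos + int(delta_arr[max(idx, 0)])

    return lift


def simulate_haplotype(spec: FixtureSpec) -> HaplotypeFixture:
    """Build a full fixture bundle from one deterministic generator stream."""
    rng = np.random.default_rng(spec.seed)
    first_field, paralog = DR_PLANS[spec.dr_plan]
    loci = list(spec.loci)
    if paralog and paralog not in loci:
        loci.append(paralog)

    locus_fixtures: list[_Locus] = []
    for locus in loci:
        ff = first_field if locus == "DRB1" else _FIRST_FIELDS.get(locus, "01")
        locus_fixtures.append(
            simulate_locus(rng, locus, ff, n_alleles=spec.n_alleles_per_locus)
        )

    c4ref, motif_span = make_c4_reference(rng, herv_length=spec.herv_length)
    cassettes = [
        cassette_sequence(c4ref, motif_span, iso, herv) for iso, herv in spec.c4_plan
    ]

    # layout: genes in order, C4 cassettes between the class I and class II
    # blocks, separated by random spacers of at least 1.5 kb
    features: list[tuple[str, str, str]] = []  # (kind, name, seq on + strand)
    for i, lf in enumerate(locus_fixtures):
        strand = "+" if i % 2 == 0 else "-"
        seq = lf.model.genomic_sequence
        features.append(("gene", lf.name, seq if strand == "+" else revcomp(seq)))
        if i == 2:  # after the class I block
            for j, cas in enumerate(cassettes):
                features.append(("c4", f"C4#{j}", cas))
    total_feature = sum(len(s) for _, _, s in features)
    n_spacers = len(features) + 1
    slack = spec.length - total_feature - 1500 * n_spacers
    if slack < 0:
        raise ValueError("spec.length too small for the planted features")
    cuts = np.sort(rng.integers(0, slack + 1, size=n_spacers - 1))
    spacer_lens = np.diff(np.concatenate(([0], cuts, [slack]))) + 1500

    parts = []
    gene_intervals: dict[str, tuple[int, int]] = {}
    gene_strands: dict[str, str] = {}
    c4_intervals: list[tuple[int, int]] = []
    pos = 0
    strand_by_name = {
        lf.name: ("+" if i % 2 == 0 else "-") for i, lf in enumerate(locus_fixtures)
    }
    for i, (kind, name, seq) in enumerate(features):
        spacer = random_sequence(rng, int(spacer_lens[i]))
        parts.append(spacer)
        pos += len(spacer)
        parts.append(seq)
        if kind == "gene":
            gene_intervals[name] = (pos, pos + len(seq))
            gene_strands[name] = strand_by_name[name]
        else:
            c4_intervals.append((pos, pos + len(seq)))
        pos += len(seq)
    parts.append(random_sequence(rng, int(spacer_lens[-1])))
    ancestor = "".join(parts)

    # truth exon coordinates on the haplotype
    gene_exons: dict[str, list[tuple[int, int]]] = {}
    for lf in locus_fixtures:
        start, end = gene_intervals[lf.name]
        glen = len(lf.model.genomic_sequence)
        if gene_strands[lf.name] == "+":
            gene_exons[f"HLA-{lf.name}"] = [(start + s, start + e) for s, e in lf.model.exons]
        else:
            gene_exons[f"HLA-{lf.name}"] = sorted(
                (start + glen - e, start + glen - s) for s, e in lf.model.exons
            )

    # variant planting in spacers only, so gene/C4 truth also holds on the assembly
    feature_spans = sorted(list(gene_intervals.values()) + c4_intervals)
    allowed = []
    prev = 0
    for s, e in feature_spans:
        allowed.append((prev, s))
        prev = e
    allowed.append((prev, len(ancestor)))
    derived, alignment, edit_truth = _plant_edits(
        rng, ancestor, allowed, spec.variant_plan
    )

    # planted features keep their content but shift coordinates once edits
    # are applied; lift all truth coordinates from ancestor to assembly space
    lift = _lift_factory(alignment.cigar)
    gene_intervals = {n: (lift(s), lift(e)) for n, (s, e) in gene_intervals.items()}
    gene_exons = {
        n: [(lift(s), lift(e)) for s, e in exons] for n, exons in gene_exons.items()
    }
    c4_intervals = [(lift(s), lift(e)) for s, e in c4_intervals]

    # planted repeats on the assembly (coordinates only; content is background)
    repeats = []
    families = ["LINE/L1", "SINE/Alu", "LTR/ERV1", "Retroposon/SVA"]
    for i in range(spec.n_repeats):
        length = int(rng.integers(200, 2000))
        start = int(rng.integers(0, max(1, len(derived) - length)))
        repeats.append(
            RepeatFeature(
                seq_id="assembly",
                start=start,
                end=start + length,
                repeat_name=f"rep{i}",
                repeat_class_family=families[i % len(families)],
                strand="+" if i % 2 == 0 else "-",
            )
        )
    merged: list[tuple[int, int]] = []
    for s, e in sorted((f.start, f.end) for f in repeats):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    rep_fraction = sum(e - s for s, e in merged) / len(derived)

    dra = gene_intervals.get("DRA")
    drb1 = gene_intervals.get("DRB1")
    class2 = (
        (min(dra), min(len(derived), max(drb1) + 20_000)) if dra and drb1 else (0, 0)
    )

    allele_db = [a for lf in locus_fixtures for a in lf.alleles]
    allele_fasta = "".join(
        f">{a.allele_name}\n{a.sequence}\n" for a in allele_db
    )
    truth = TruthTable(
        chosen_alleles={lf.name: lf.alleles[0].allele_name for lf in locus_fixtures},
        gene_exons=gene_exons,
        gene_strands={f"HLA-{n}": s for n, s in gene_strands.items()},
        gene_intervals={f"HLA-{n}": iv for n, iv in gene_intervals.items()},
        n_snps=len(edit_truth["snp"]),
        n_indels=len(edit_truth["indel"]),
        n_svs=len(edit_truth["sv"]),
        snp_positions=sorted(edit_truth["snp"]),
        c4_genotype=",".join(iso + herv for iso, herv in spec.c4_plan),
        c4_intervals=c4_intervals,
        dr_group=spec.dr_plan,
        class2_interval=class2,
        repeat_fraction=rep_fraction,
        allele_distances={
            name: d for lf in locus_fixtures for name, d in lf.distances.items()
        },
    )
    return HaplotypeFixture(
        spec=spec,
        reference=SequenceRecord("reference", "pre-variant ancestor", ancestor),
        assembly=SequenceRecord("assembly", "haplotype with planted variants", derived),
        alignment=alignment,
        allele_db=allele_db,
        allele_fasta=allele_fasta,
        locus_msas={lf.name: lf.msa_text for lf in locus_fixtures},
        gene_models=[lf.model for lf in locus_fixtures],
        c4_reference=c4ref,
        repeats=repeats,
        truth=truth,
    )


def simulate_pileups(
    assembly: str, plan: PileupPlan, seed: int = 0
) -> list[PileupColumn]:
    """Per-technology pileup columns over the whole assembly.

    Clean columns carry the assembly base plus capped sequencing noise (the
    noise can never reach a majority). At planted discordance positions the
    stated majority base gets the stated fraction of the column depth.
    """
    rng = np.random.default_rng(seed)
    discordant = {pos: (base, fracs) for pos, base, fracs in plan.discordances}
    for pos, (base, fracs) in discordant.items():
        for tech, frac in fracs.items():
            if plan.depths.get(tech, 0) == 0:
                raise ValueError(f"discordance at {pos} requires depth for {tech}")
    columns = []
    alt_of = {"A": "C", "C": "G", "G": "T", "T": "A"}
    for pos, ref_base in enumerate(assembly):
        counts: dict[str, dict[str, int]] = {}
        if pos in discordant:
            base, fracs = discordant[pos]
            for tech, depth in plan.depths.items():
                frac = fracs.get(tech, 0.0)
                k = int(round(frac * depth))
                counts[tech] = {base: k}
                if depth - k:
                    counts[tech][ref_base if ref_base != base else alt_of[base]] = depth - k
        else:
            for tech, depth in plan.depths.items():
                errors = min(int(rng.binomial(depth, plan.error_rate)), max(depth // 3 - 1, 0))
                counts[tech] = {ref_base: depth - errors}
                if errors:
                    counts[tech][alt_of[ref_base]] = errors
        columns.append(PileupColumn(pos=pos, counts=counts))
    return columns


def plant_corruptions(
    assembly: str, n: int, seed: int = 0
) -> tuple[str, list[int]]:
    """Corrupt ``n`` random positions (substitutions); returns (seq, positions)."""
    rng = np.random.default_rng(seed)
    positions = sorted(rng.choice(len(assembly), size=n, replace=False).tolist())
    chars = list(assembly)
    for p in positions:
        old = chars[p]
        chars[p] = str(rng.choice([b for b in "ACGT" if b != old]))
    return "".join(chars), positions
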