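import numpy as np
import pytest

from mhcforge.align import AlignmentRecord
from mhcforge.annotation import (
    GeneModel,
    annotate_assembly,
    check_translation,
    edlib_alignment_provider,
    place_gene,
    project_exons,
    select_reference,
)
from mhcforge.seq_io import SequenceRecord
from mhcforge.simulate import random_coding, random_sequence


def _model(name="G", tier="fallback", seq="ATGAAACCCTAA", exons=((0, 12),), coding=True):
    return GeneModel(name, tier, seq, list(exons), coding=coding)


class TestSelectReference:
    def test_tier_precedence(self):
        tiers = {
            "allele-db": {"G": _model(tier="allele-db")},
            "curated-genomic": {"G": _model(tier="curated-genomic"), "H": _model("H", "curated-genomic")},
            "fallback": {"G": _model(), "H": _model("H"), "K": _model("K")},
        }
        assert select_reference("G", tiers).tier == "allele-db"
        assert select_reference("H", tiers).tier == "curated-genomic"
        assert select_reference("K", tiers).tier == "fallback"

    def test_missing_gene_error(self):
        with pytest.raises(KeyError):
            select_reference("Z", {"fallback": {}})


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(21)
    cds = "ATG" + random_coding(rng, 40) + "TAA"
    exons = [(0, 60), (210, len(cds) + 150)]
    gene = cds[:60] + random_sequence(rng, 150) + cds[60:]
    assembly = SequenceRecord(
        "asm", "", random_sequence(rng, 4000) + gene + random_sequence(rng, 4000)
    )
    model = GeneModel("G1", "allele-db", gene, exons)
    return model, assembly, 4000


class TestPlaceGene:
    def test_perfect_copy_placed_at_planted_coordinates(self, planted):
        model, assembly, offset = planted
        provider = edlib_alignment_provider()
        placement = place_gene(model, assembly, provider(model.genomic_sequence, assembly))
        assert placement is not None
        assert (placement.t_start, placement.t_end) == (
            offset,
            offset + len(model.genomic_sequence),
        )

    def test_three_prime_deletion_gives_no_annotation(self, planted):
        model, _, _ = planted
        rng = np.random.default_rng(22)
        glen = len(model.genomic_sequence)
        truncated_copy = model.genomic_sequence[: int(glen * 0.7)]
        assembly = SequenceRecord(
            "asm", "", random_sequence(rng, 3000) + truncated_copy + random_sequence(rng, 3000)
        )
        provider = edlib_alignment_provider()
        assert place_gene(model, assembly, provider(model.genomic_sequence, assembly)) is None

    def test_segmental_duplicate_higher_score_then_lower_coordinate(self, planted):
        model, _, _ = planted
        rng = np.random.default_rng(23)
        gene = model.genomic_sequence
        mutated = list(gene)
        mutated[100] = "A" if gene[100] != "A" else "C"
        assembly = SequenceRecord(
            "asm",
            "",
            random_sequence(rng, 2000) + "".join(mutated) + random_sequence(rng, 2000)
            + gene + random_sequence(rng, 2000),
        )
        provider = edlib_alignment_provider()
        # the exact copy (second) outscores the mutated first copy
        records = []
        for rec in provider(gene, assembly):
            records.append(rec)
        # edlib returns one best placement; locate both copies via masking
        placement = place_gene(model, assembly, records)
        assert placement.t_start == 2000 + len(gene) + 2000

    def test_tie_broken_by_lower_coordinate(self, planted):
        model, _, _ = planted
        gene = model.genomic_sequence
        recs = [
            AlignmentRecord("q", "asm", 0, len(gene), s, s + len(gene),
                            cigar=[(len(gene), "=")], n_matches=len(gene),
                            block_length=len(gene), score=100.0)
            for s in (5000, 1000)
        ]
        assert place_gene(model, SequenceRecord("asm", "", "A" * 10000), recs).t_start == 1000


def _placement(cigar, t_start=100, strand="+", qlen=None):
    q_span = sum(n for n, op in cigar if op in "=XI")
    t_span = sum(n for n, op in cigar if op in "=XD")
    return AlignmentRecord(
        "q", "t", 0, q_span, t_start, t_start + t_span, strand=strand,
        cigar=cigar, n_matches=sum(n for n, op in cigar if op == "="),
        block_length=sum(n for n, op in cigar),
    )


class TestProjectExons:
    def test_identity_alignment_shifts_by_offset(self):
        model = _model(seq="A" * 100, exons=[(10, 30), (50, 90)])
        exons = project_exons(model, _placement([(100, "=")], t_start=500))
        assert exons == [(510, 530), (550, 590)]

    def test_assembly_insertion_inside_intron_shifts_downstream_exon(self):
        model = _model(seq="A" * 100, exons=[(10, 30), (50, 90)])
        # 10 bp extra assembly sequence inside the intron (D consumes target)
        cigar = [(40, "="), (10, "D"), (60, "=")]
        exons = project_exons(model, _placement(cigar, t_start=0))
        assert exons == [(10, 30), (60, 100)]  # exon lengths unchanged

    def test_boundary_inside_assembly_deletion_snaps_left(self):
        model = _model(seq="A" * 100, exons=[(10, 30), (49, 90)])
        # assembly lacks query bases 48..52 (I consumes query only)
        cigar = [(48, "="), (4, "I"), (48, "=")]
        exons = project_exons(model, _placement(cigar, t_start=0))
        assert exons[1][0] == 47  # snapped to last aligned assembly coordinate

    def test_incomplete_placement_rejected(self):
        model = _model(seq="A" * 100, exons=[(10, 30)])
        partial = AlignmentRecord("q", "t", 5, 100, 0, 95, cigar=[(95, "=")],
                                  n_matches=95, block_length=95)
        with pytest.raises(ValueError, match="complete"):
            project_exons(model, partial)


class TestCheckTranslation:
    def test_intact_gene_consistent(self, planted):
        model, assembly, offset = planted
        exons = [(offset + s, offset + e) for s, e in model.exons]
        assert check_translation(exons, "+", assembly) == "consistent"

    def test_premature_stop_detected(self, planted):
        model, assembly, offset = planted
        seq = list(assembly.residues)
        # plant TAG at an in-frame codon inside exon 1
        seq[offset + 9 : offset + 12] = "TAG"
        mutated = SequenceRecord("asm", "", "".join(seq))
        exons = [(offset + s, offset + e) for s, e in model.exons]
        assert check_translation(exons, "+", mutated) == "premature-stop"

    @pytest.mark.parametrize(
        "edit,verdict",
        [((0, "CTG"), "start-missing"), ((-3, "AAA"), "stop-missing")],
    )
    def test_terminal_codon_failures(self, planted, edit, verdict):
        model, assembly, offset = planted
        pos, repl = edit
        cds_positions = [p for s, e in model.exons for p in range(offset + s, offset + e)]
        targets = cds_positions[:3] if pos == 0 else cds_positions[-3:]
        seq = list(assembly.residues)
        for p, c in zip(targets, repl):
            seq[p] = c
        assert check_translation(
            [(offset + s, offset + e) for s, e in model.exons], "+", SequenceRecord("a", "", "".join(seq))
        ) == verdict


class TestAnnotateAssembly:
    def test_recovers_planted_exons_exactly(self, small_bundle):
        fx = small_bundle
        anns = annotate_assembly(fx.assembly, fx.gene_models)
        assert len(anns) == len(fx.gene_models)
        for ann in anns:
            assert ann.exons == fx.truth.gene_exons[ann.gene_name]
            assert ann.verdict == "consistent"
        starts = [a.start for a in anns]
        assert starts == sorted(starts)

    def test_disrupted_genes_suppressed(self, small_bundle):
        fx = small_bundle
        # nonsense-mutate one planted gene copy in the assembly
        name = fx.gene_models[0].gene_name
        exon0 = fx.truth.gene_exons[name][0]
        strand = fx.truth.gene_strands[name]
        seq = list(fx.assembly.residues)
        if strand == "+":
            seq[exon0[0] + 6 : exon0[0] + 9] = "TAA"
        else:
            last = fx.truth.gene_exons[name][-1]
            seq[last[1] - 9 : last[1] - 6] = "TTA"
        mutated = SequenceRecord("asm", "", "".join(seq))
        anns = annotate_assembly(mutated, fx.gene_models)
        assert len(anns) == len(fx.gene_models) - 1
        assert name not in {a.gene_name for a in anns}

    def test_exception_list_keeps_failing_gene_with_verdict(self, small_bundle):
        fx = small_bundle
        name = fx.gene_models[0].gene_name
        exon0 = fx.truth.gene_exons[name][0]
        strand = fx.truth.gene_strands[name]
        seq = list(fx.assembly.residues)
        if strand == "+":
            seq[exon0[0] + 6 : exon0[0] + 9] = "TAA"
        else:
            last = fx.truth.gene_exons[name][-1]
            seq[last[1] - 9 : last[1] - 6] = "TTA"
        mutated = SequenceRecord("asm", "", "".join(seq))
        anns = annotate_assembly(mutated, fx.gene_models, exception_genes={name})
        kept = next(a for a in anns if a.gene_name == name)
        assert kept.verdict == "premature-stop"

    def test_pseudogene_skips_translation_check(self):
        rng = np.random.default_rng(30)
        body = random_sequence(rng, 600)  # no valid ORF expected
        model = GeneModel("PSEUDO", "fallback", body, [(0, 600)], coding=False)
        assembly = SequenceRecord(
            "asm", "", random_sequence(rng, 2000) + body + random_sequence(rng, 2000)
        )
        anns = annotate_assembly(assembly, [model])
        assert len(anns) == 1
        assert anns[0].verdict is None

    def test_empty_gene_set(self, small_bundle):
        assert annotate_assembly(small_bundle.assembly, []) == []
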