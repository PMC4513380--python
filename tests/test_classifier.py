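"""Stepwise decision pipeline: ordered rules, precedence, batch behaviour."""

import itertools

import numpy as np
import pytest

from conftest import aln_with_counts, gene_from_protein
from mispath import classifier
from mispath.io import GeneBundle
from mispath.synthetic import make_nucleotide_alignment
from mispath.types import (
    Classification,
    GeneRecord,
    KnownVariantRecord,
    Label,
    PhenotypeStatus,
    PipelineConfig,
    Reason,
    VariantQuery,
)


def ordered_rules_oracle(stop_auto, hotspot, wpc, psic, cfg):
    """Independent restatement of the ordered decision rules."""
    if cfg.use_stop_gain and stop_auto:
        return (Label.PATHOGENIC, Reason.STOP_GAIN)
    if cfg.use_hotspot and not hotspot:
        return (Label.BENIGN_H, Reason.NO_HOTSPOT)
    if cfg.use_psic and psic is not None and psic < cfg.psic_cutoff:
        return (Label.BENIGN_A, Reason.PSIC_LOW)
    cutoff = cfg.wpc_cutoff_with_psic if cfg.use_psic else cfg.wpc_cutoff_default
    if wpc >= cutoff:
        return (Label.PATHOGENIC, Reason.WPC_HIGH)
    return (Label.BENIGN_A, Reason.WPC_LOW)


class TestDecisionTable:
    def test_every_branch_combination_matches_oracle(self):
        """Exhaustive sweep incl. exact-boundary WPC (40, 49) and PSIC (1.03)."""
        wpc_values = [0.0, 39.9, 40.0, 48.9, 49.0, 75.0, 100.0]
        psic_values = [None, 0.0, 0.5, 1.02, 1.03, 1.04, 2.0]
        combos = itertools.product(
            [False, True],  # stop_auto
            [False, True],  # hotspot
            [False, True],  # use_psic
            [False, True],  # use_hotspot
            [False, True],  # use_stop_gain
            wpc_values,
            psic_values,
        )
        for stop, hot, up, uh, us, wpc, psic in combos:
            cfg = PipelineConfig(use_psic=up, use_hotspot=uh, use_stop_gain=us)
            got = classifier.decide(
                stop_gain_auto=stop, hotspot=hot, wpc=wpc, psic=psic, config=cfg
            )
            assert got == ordered_rules_oracle(stop, hot, wpc, psic, cfg), (
                stop, hot, up, uh, us, wpc, psic,
            )

    def test_boundary_wpc_49_vs_48_9_default_mode(self):
        cfg = PipelineConfig()
        assert classifier.decide(
            stop_gain_auto=False, hotspot=True, wpc=49.0, psic=None, config=cfg
        ) == (Label.PATHOGENIC, Reason.WPC_HIGH)
        assert classifier.decide(
            stop_gain_auto=False, hotspot=True, wpc=48.9, psic=None, config=cfg
        ) == (Label.BENIGN_A, Reason.WPC_LOW)

    def test_raising_wpc_cutoff_never_creates_pathogenic(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            wpc = float(rng.random() * 100)
            labels = []
            for cut in range(0, 101, 5):
                cfg = PipelineConfig(wpc_cutoff_default=float(cut))
                lab, _ = classifier.decide(
                    stop_gain_auto=False, hotspot=True, wpc=wpc, psic=None,
                    config=cfg,
                )
                labels.append(lab)
            # pathogenic labels form a prefix: once benign, higher cutoffs stay benign
            seen_benign = False
            for lab in labels:
                if lab != Label.PATHOGENIC:
                    seen_benign = True
                assert not (seen_benign and lab == Label.PATHOGENIC)


def _records(gene="TG1", positions=(5,), phen="DiseaseX"):
    return [
        KnownVariantRecord(
            gene=gene, prot_pos=p, ref_aa="A", alt_aa="V",
            classification=Classification.PATHOGENIC, phenotype=phen,
        )
        for p in positions
    ]


class TestClassify:
    def setup_method(self):
        self.gene = gene_from_protein("MKTWAYCDEFGHIKLNPQRS", seed=5)
        self.pos = 6  # residue Y
        self.ref = self.gene.protein_seq[self.pos - 1]

    def query(self, alt="F"):
        return VariantQuery(
            gene=self.gene.symbol, prot_pos=self.pos, ref_aa=self.ref, alt_aa=alt
        )

    def test_no_literature_gene_is_benign_h(self):
        aln = aln_with_counts(self.gene, self.pos, matching=10, mismatching=0)
        res = classifier.classify(self.query(), self.gene, aln, [], PipelineConfig())
        assert res.label == Label.BENIGN_H
        assert res.reason == Reason.NO_HOTSPOT
        assert res.phenotype.status == PhenotypeStatus.NO_DATA

    def test_hotspot_high_wpc_is_pathogenic_with_phenotype(self):
        aln = aln_with_counts(self.gene, self.pos, matching=10, mismatching=0)
        res = classifier.classify(
            self.query(), self.gene, aln, _records(), PipelineConfig()
        )
        assert res.label == Label.PATHOGENIC and res.reason == Reason.WPC_HIGH
        assert res.wpc == 100.0
        assert res.phenotype.phenotype == "DiseaseX"

    def test_wpc_boundary_49_pathogenic_48_benign(self):
        cfg = PipelineConfig()
        aln = aln_with_counts(self.gene, self.pos, matching=49, mismatching=51)
        res = classifier.classify(self.query(), self.gene, aln, _records(), cfg)
        assert res.label == Label.PATHOGENIC and res.wpc == pytest.approx(49.0)
        aln = aln_with_counts(self.gene, self.pos, matching=48, mismatching=52)
        res = classifier.classify(self.query(), self.gene, aln, _records(), cfg)
        assert res.label == Label.BENIGN_A and res.reason == Reason.WPC_LOW

    def test_psic_gate_classifies_tolerated_substitution_benign(self):
        # half the homologs already carry the alternate residue: low delta
        cfg = PipelineConfig(use_psic=True)
        human = self.gene.protein_seq
        rng = np.random.default_rng(1)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        homologs = []
        for i in range(30):
            row = list("".join(rng.choice(aa, len(human))))
            row[self.pos - 1] = self.ref if i % 2 == 0 else "F"
            homologs.append("".join(row))
        from conftest import protein_alignment

        aln = protein_alignment(human, homologs)
        res = classifier.classify(self.query("F"), self.gene, aln, _records(), cfg)
        assert res.label == Label.BENIGN_A and res.reason == Reason.PSIC_LOW
        assert res.psic < 1.03

    def test_psic_pass_then_wpc_40_pathogenic(self):
        # deep conserved column: large delta, full WPC, cutoff 40 applies
        cfg = PipelineConfig(use_psic=True)
        rng = np.random.default_rng(2)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        human = self.gene.protein_seq
        homologs = []
        for _ in range(30):
            row = list("".join(rng.choice(aa, len(human))))
            row[self.pos - 1] = self.ref
            homologs.append("".join(row))
        from conftest import protein_alignment

        aln = protein_alignment(human, homologs)
        res = classifier.classify(self.query("W"), self.gene, aln, _records(), cfg)
        assert res.psic > 1.03
        assert res.label == Label.PATHOGENIC and res.reason == Reason.WPC_HIGH

    def test_hotspot_off_mode_never_benign_h(self):
        cfg = PipelineConfig(use_hotspot=False)
        aln = aln_with_counts(self.gene, self.pos, matching=1, mismatching=9)
        res = classifier.classify(self.query(), self.gene, aln, [], cfg)
        assert res.label == Label.BENIGN_A
        assert res.phenotype.status == PhenotypeStatus.NO_DATA


class TestStopGain:
    def make_gene(self, junction_offset: int) -> tuple[GeneRecord, int]:
        """Gene with a W (TGG) codon whose start is `junction_offset` nt
        upstream of the last exon-exon junction."""
        protein = "M" + "".join(
            "ACDEFGHIKLNPQRSTV"[i % 17] for i in range(58)
        ) + "W"
        protein += "".join("ACDEFGHIKLNPQRSTV"[(i * 7) % 17] for i in range(40))
        gene = gene_from_protein(protein, seed=9)
        w_pos = 60
        codon_start = 3 * (w_pos - 1) + 1
        junction = codon_start + junction_offset
        exons = (junction, len(gene.cds_seq) - junction)
        return (
            GeneRecord(gene.symbol, gene.protein_seq, gene.cds_seq, exons),
            w_pos,
        )

    def test_nmd_stop_gain_overrides_low_wpc(self):
        gene, pos = self.make_gene(junction_offset=120)
        aln = aln_with_counts(gene, pos, matching=0, mismatching=10)
        q = VariantQuery(gene=gene.symbol, prot_pos=pos, ref_aa="W", alt_aa="*")
        res = classifier.classify(q, gene, aln, [], PipelineConfig())
        assert res.label == Label.PATHOGENIC and res.reason == Reason.STOP_GAIN
        assert res.wpc == 0.0

    def test_near_junction_stop_falls_through_to_pipeline(self):
        gene, pos = self.make_gene(junction_offset=30)
        aln = aln_with_counts(gene, pos, matching=10, mismatching=0)
        q = VariantQuery(gene=gene.symbol, prot_pos=pos, ref_aa="W", alt_aa="*")
        res = classifier.classify(q, gene, aln, [], PipelineConfig())
        assert res.label == Label.BENIGN_H  # no literature: hotspot gate fires
        recs = _records(gene=gene.symbol, positions=(pos - 3,))
        res = classifier.classify(q, gene, aln, recs, PipelineConfig(use_psic=True))
        # stop-gains are never PSIC-scored; WPC 100 >= 40 decides
        assert res.psic is None
        assert res.label == Label.PATHOGENIC and res.reason == Reason.WPC_HIGH

    def test_stop_gain_toggle_off_ignores_nmd(self):
        gene, pos = self.make_gene(junction_offset=120)
        aln = aln_with_counts(gene, pos, matching=0, mismatching=10)
        q = VariantQuery(gene=gene.symbol, prot_pos=pos, ref_aa="W", alt_aa="*")
        cfg = PipelineConfig(use_stop_gain=False)
        res = classifier.classify(q, gene, aln, [], cfg)
        assert res.label == Label.BENIGN_H


class TestBatch:
    def make_bundle(self, symbol="BG1", seed=3):
        gene = gene_from_protein("MKTWAYCDEFGHIKLNPQRS", symbol=symbol, seed=seed)
        aln = aln_with_counts(gene, 6, matching=8, mismatching=2)
        rows = tuple(
            (("HUMAN|" + symbol) if rid == "HUMAN" else rid, seq)
            for rid, seq in aln.rows
        )
        from mispath.types import MultipleAlignment

        aln = MultipleAlignment(
            kind="protein", rows=rows, human_row_id="HUMAN|" + symbol
        )
        return GeneBundle(gene=gene, combined_protein=aln)

    def test_batch_matches_per_query_classify(self):
        b1, b2 = self.make_bundle("BG1"), self.make_bundle("BG2", seed=4)
        bundles = {"BG1": b1, "BG2": b2}
        records = _records("BG1") + _records("BG2", positions=(3,))
        rows = [("BG1", "p.Y6W"), ("BG2", "p.Y6C"), ("BG1", "p.M1V")]
        cfg = PipelineConfig()
        results, errors = classifier.classify_batch(rows, bundles, records, cfg)
        assert not errors
        assert [r.query.short() for r in results] == [
            "BG1:p.Y6W", "BG2:p.Y6C", "BG1:p.M1V",
        ]
        for (sym, text), res in zip(rows, results):
            from mispath.io import parse_variant_query

            q = parse_variant_query(text, bundles[sym].gene)
            solo = classifier.classify(
                q, bundles[sym].gene, bundles[sym].combined_protein, records, cfg
            )
            assert solo == res

    def test_malformed_row_isolated(self):
        bundles = {"BG1": self.make_bundle("BG1")}
        rows = [
            ("BG1", "p.Y6W"),
            ("BG1", "p.W6Y"),   # ref mismatch
            ("NOPE", "p.M1V"),  # unknown gene
            ("BG1", "garbage"),
            ("BG1", "p.M1V"),
        ]
        results, errors = classifier.classify_batch(
            rows, bundles, _records("BG1"), PipelineConfig()
        )
        assert len(results) == 2
        assert sorted(e.row_index for e in errors) == [1, 2, 3]


class TestConservationReport:
    def test_ambiguous_mapping_blanks_nucleotide_columns(self):
        protein = "MSTWAYCDEFGHIKLNPQRS"
        gene = gene_from_protein(protein, seed=1)
        cds = gene.cds_seq[:3] + "AGC" + gene.cds_seq[6:]  # Ser codon AGC at pos 2
        gene = GeneRecord(gene.symbol, gene.protein_seq, cds, gene.exons)
        paln = aln_with_counts(gene, 2, matching=6, mismatching=2)
        naln = make_nucleotide_alignment(gene, paln, seed=2, source="ortholog")
        bundle = GeneBundle(
            gene=gene,
            combined_protein=paln,
            ortholog_protein=paln,
            ortholog_nucleotide=naln,
        )
        cfg = PipelineConfig()
        q = VariantQuery(gene=gene.symbol, prot_pos=2, ref_aa="S", alt_aa="R")
        rep = classifier.conservation_report(q, bundle, _records(gene.symbol), cfg)
        assert rep.nucleotide_ortholog_pct is None  # two causal edits possible
        assert rep.protein_ortholog_pct == pytest.approx(75.0)
        # unambiguous variant fills the nucleotide column
        q2 = VariantQuery(gene=gene.symbol, prot_pos=1, ref_aa="M", alt_aa="V")
        rep2 = classifier.conservation_report(q2, bundle, [], cfg)
        assert rep2.nucleotide_ortholog_pct is not None

    def test_report_wpc_equals_classify_wpc(self):
        gene = gene_from_protein("MKTWAYCDEFGHIKLNPQRS", seed=6)
        aln = aln_with_counts(gene, 6, matching=3, mismatching=5)
        bundle = GeneBundle(gene=gene, combined_protein=aln)
        q = VariantQuery(gene=gene.symbol, prot_pos=6, ref_aa="Y", alt_aa="W")
        cfg = PipelineConfig()
        rep = classifier.conservation_report(q, bundle, [], cfg)
        res = classifier.classify(q, gene, aln, [], cfg)
        assert rep.wpc == res.wpc

    def test_fully_conserved_fixture_reports_100(self):
        gene = gene_from_protein("MKTWAYCDEFGHIKLNPQRS", seed=6)
        aln = aln_with_counts(gene, 6, matching=10, mismatching=0)
        naln = make_nucleotide_alignment(gene, aln, seed=1)
        bundle = GeneBundle(
            gene=gene,
            combined_protein=aln,
            ortholog_protein=aln,
            paralog_protein=aln,
            ortholog_nucleotide=naln,
            paralog_nucleotide=naln,
        )
        # Y -> C is reachable by a unique codon edit, so DNA columns fill in
        q = VariantQuery(gene=gene.symbol, prot_pos=6, ref_aa="Y", alt_aa="C")
        rep = classifier.conservation_report(q, bundle, [], PipelineConfig())
        assert rep.wpc == 100.0
        assert rep.protein_ortholog_pct == 100.0
        assert rep.protein_paralog_pct == 100.0
        assert rep.nucleotide_ortholog_pct == 100.0
        assert rep.nucleotide_paralog_pct == 100.0
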