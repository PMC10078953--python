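"""Generator contracts: determinism, parseability, planted-signal layout."""

import filecmp
from collections import Counter

import numpy as np
import pytest

from lncsynt import synthetic_data as sd
from lncsynt import tf_enrichment as tfe
from lncsynt.core_io import parse_chain, parse_gene_annotation, parse_score_track
from lncsynt.synthetic_data import CLASSES, CONSERVED_CLASSES


def test_fixture_outputs_byte_identical_across_reruns(tmp_path):
    cfg = sd.SimulationConfig(seed=11)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    sd.write_fixture(sd.generate_genome_pair(cfg), d1)
    sd.write_fixture(sd.generate_genome_pair(sd.SimulationConfig(seed=11)), d2)
    files = sorted(p.name for p in d1.iterdir())
    match, mismatch, errors = filecmp.cmpfiles(d1, d2, files, shallow=False)
    assert mismatch == [] and errors == []
    assert set(match) == set(files)


def test_emitted_files_parse_strictly(tmp_path, fixture):
    """Every emitted file round-trips through the readers in strict mode."""
    out = tmp_path / "fix"
    sd.write_fixture(fixture, out)
    genes = parse_gene_annotation(out / "human.gtf", species="human")
    assert len(genes) == len(fixture.genes_h)
    chains = parse_chain(out / "human_to_mouse.chain")   # validates invariants
    assert len(chains) == len(fixture.chains_h2m)
    track = parse_score_track(out / "human.phastcons.bedgraph", strict=True)
    g = fixture.lnc("human")[0]
    sp = g.span
    assert np.allclose(
        track.values(sp.chrom, sp.start, sp.end),
        fixture.track_h.values(sp.chrom, sp.start, sp.end),
    )


def test_truth_classes_exclusive_and_complete(fixture):
    truth = fixture.truth
    lnc_ids = {g.gene_id for g in fixture.lnc("human")} | {
        g.gene_id for g in fixture.lnc("mouse")
    }
    assert set(truth.lnc_class) == lnc_ids
    per_class = Counter(
        truth.lnc_class[g.gene_id] for g in fixture.lnc("human")
    )
    assert per_class == fixture.cfg.n_lnc_per_class
    # paired classes map exactly once
    assert len(set(truth.pair_map.values())) == len(truth.pair_map)
    for cls in CONSERVED_CLASSES:
        assert len(truth.pairs_of_class(cls)) == fixture.cfg.n_lnc_per_class[cls]


def test_full_identity_sequence_class_pairs():
    cfg = sd.SimulationConfig(
        seed=5,
        identity_conserved=1.0,
        n_lnc_per_class={c: (3 if c == "sequence" else 0) for c in CLASSES},
        n_coding_pairs=12,
    )
    fix = sd.generate_genome_pair(cfg)
    sh, sm = fix.lnc_sequences("human"), fix.lnc_sequences("mouse")
    for h, m in fix.truth.pairs_of_class("sequence"):
        assert sh[h] == sm[m]


def test_sizing_error_when_genome_too_small():
    cfg = sd.SimulationConfig(seed=0, genome_length=400_000)
    with pytest.raises(ValueError, match="too small"):
        sd.generate_genome_pair(cfg)


def test_nonconserved_lncRNAs_carry_denser_repeats(fixture):
    from lncsynt.annotation_features import te_content

    truth = fixture.truth
    te = {
        g.gene_id: te_content(g, fixture.repeats_h, "whole")
        for g in fixture.lnc("human")
    }
    cons = [v for g, v in te.items() if truth.lnc_class[g] in CONSERVED_CLASSES]
    non = [v for g, v in te.items() if truth.lnc_class[g] == "nonconserved"]
    assert np.mean(non) > np.mean(cons)


# ---------------------------------------------------------------------------
# expression generator
# ---------------------------------------------------------------------------

def test_planted_tissue_specific_fraction(expression_data, fixture):
    from lncsynt.expression import cpm_normalize, tissue_specificity

    tissue_em, _ = expression_data
    prof = tissue_specificity(cpm_normalize(tissue_em), tissue_em.sample_labels)
    spec = [g for g, t in fixture.truth.tissue_specific.items() if t]
    assert spec
    assert prof.loc[spec, "max_fraction"].median() > 0.8


def test_full_concentration_gives_max_fraction_one():
    cfg = sd.SimulationConfig(seed=9, specific_fraction=1.0)
    fix = sd.generate_genome_pair(cfg)
    tissue_em, _ = sd.generate_expression(cfg, fix)
    from lncsynt.expression import cpm_normalize, tissue_specificity

    prof = tissue_specificity(cpm_normalize(tissue_em), tissue_em.sample_labels)
    spec = [
        g for g, t in fix.truth.tissue_specific.items()
        if t and g in prof.index
    ]
    assert spec
    assert prof.loc[spec, "max_fraction"].min() > 0.99


def test_planted_neighbor_correlation_realized(expression_data, fixture):
    from lncsynt.expression import cpm_normalize, spearman

    tissue_em, _ = expression_data
    cpm = cpm_normalize(tissue_em)
    rhos = []
    for l, m in fixture.truth.neighbor_pairs:
        if fixture.truth.lnc_class[l] in CONSERVED_CLASSES and m in cpm.index:
            rhos.append(spearman(cpm.loc[l], cpm.loc[m]))
    assert 0.80 <= float(np.median(rhos)) <= 0.97


def test_null_de_effect_gives_no_differential_calls():
    from lncsynt.perturbation import de_test

    cfg = sd.SimulationConfig(seed=13, de_effect=0.0)
    fix = sd.generate_genome_pair(cfg)
    _, pem = sd.generate_expression(cfg, fix)
    ctrl = pem.counts[
        [s for s in pem.sample_ids if pem.sample_labels[s] == "control"]
    ]
    trt = pem.counts[
        [s for s in pem.sample_ids if pem.sample_labels[s] == "oe_TF01"]
    ]
    res = de_test(ctrl, trt, test="nb_wald")
    assert res.regulated.mean() <= 0.05


def test_too_few_tissues_rejected(fixture):
    cfg = sd.SimulationConfig(seed=0, n_tissues=1)
    with pytest.raises(ValueError, match="tissue"):
        sd.generate_expression(cfg, fixture)


# ---------------------------------------------------------------------------
# motif generator
# ---------------------------------------------------------------------------

def test_no_enrichment_effect_balances_occurrence_rates():
    cfg = sd.SimulationConfig(seed=17, enrichment_effect=0.0)
    fix = sd.generate_genome_pair(cfg)
    motifs, prom_h, _, _ = sd.generate_motif_data(cfg, fix)
    truth = fix.truth
    sub = [m for m in motifs if truth.motif_enriched[m.motif_id]][:2]
    occ = tfe.scan_promoter_set(sub, prom_h, p_threshold=1e-4)
    hits_by_gene = Counter(o.gene_id for o in occ)
    cons_n = non_n = cons_hit = non_hit = 0
    for g in fix.lnc("human"):
        has = hits_by_gene.get(g.gene_id, 0) > 0
        if truth.lnc_class[g.gene_id] in CONSERVED_CLASSES:
            cons_n += 1
            cons_hit += has
        else:
            non_n += 1
            non_hit += has
    _, p = tfe.two_proportion_z(cons_hit, cons_n, non_hit, non_n)
    assert p > 0.001


def test_motif_longer_than_promoter_rejected(fixture):
    cfg = sd.SimulationConfig(seed=0, motif_width=600)
    with pytest.raises(ValueError, match="longer than promoter"):
        sd.generate_motif_data(cfg, fixture)


def test_end_to_end_enrichment_flags_planted_motifs():
    """The percentage and density screens recover the planted motifs from
    scanned promoters; null motifs stay unflagged."""
    n_per_class = {c: 10 for c in CLASSES}
    n_per_class["nonconserved"] = 50
    cfg = sd.SimulationConfig(
        seed=23, n_lnc_per_class=n_per_class, n_coding_pairs=112,
        enriched_motif_ids=("M01",), n_motifs=12,
    )
    fix = sd.generate_genome_pair(cfg)
    motifs, prom_h, _, _ = sd.generate_motif_data(cfg, fix)
    truth = fix.truth
    groups = {
        g.gene_id: (
            "cons"
            if truth.lnc_class[g.gene_id] in CONSERVED_CLASSES
            else "non"
        )
        for g in fix.lnc("human")
    }
    occ = tfe.scan_promoter_set(motifs, prom_h, p_threshold=1e-4)
    per = {
        m.motif_id: {"cons": Counter(), "non": Counter()} for m in motifs
    }
    for o in occ:
        per[o.motif_id][groups[o.gene_id]][o.gene_id] += 1
    cons_ids = [g for g, grp in groups.items() if grp == "cons"]
    non_ids = [g for g, grp in groups.items() if grp == "non"]
    A = {m: len(per[m]["cons"]) for m in per}
    C = {m: len(per[m]["non"]) for m in per}
    cc = {
        m: np.array([per[m]["cons"].get(g, 0) for g in cons_ids]) for m in per
    }
    cn = {
        m: np.array([per[m]["non"].get(g, 0) for g in non_ids]) for m in per
    }
    pct = tfe.enrichment_percentage(A, len(cons_ids), C, len(non_ids))
    den = tfe.enrichment_density(cc, cn)
    assert tfe.clb_tfs(pct, den) == ["M01"]


# ---------------------------------------------------------------------------
# disease catalog
# ---------------------------------------------------------------------------

def test_disease_catalog_fractions_and_vocabulary(fixture):
    from lncsynt.annotation_features import disease_by_snp

    cat = sd.generate_disease_catalog(fixture.cfg, fixture)
    assert {c for *_, c in cat.snps} <= set(fixture.cfg.disease_categories)
    flags, _ = disease_by_snp(fixture.lnc("human"), cat)
    truth = fixture.truth
    cons_flag = flags[
        [g for g in flags.index if truth.lnc_class[g] in CONSERVED_CLASSES]
    ]
    # planted fraction 0.3 of 50 conserved lncRNAs: binomial 99% interval
    assert 5 <= int(cons_flag.sum()) <= 26


def test_empty_catalog_flags_nothing(fixture):
    from lncsynt.annotation_features import DiseaseCatalog, disease_by_eqtl

    cat = DiseaseCatalog([], [], fixture.cfg.disease_categories)
    flags, _ = disease_by_eqtl(fixture.lnc("human"), cat)
    assert not flags.any()
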