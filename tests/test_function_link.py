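"""Predicted metagenome arithmetic and the phenotype-attribution screens."""

import math

import numpy as np
import pandas as pd
import pytest

from indigoferm.function_link import (CorrelationHit, GenomeContent,
                                      PathwayMap, aggregate_subpathways,
                                      contribution_day_ratio,
                                      filter_oxidoreductases,
                                      ko_phenotype_correlation,
                                      pathway_ratio_screen, predict_metagenome,
                                      taxon_contribution_share)


def _genome(d):
    return GenomeContent(copies=pd.DataFrame(d).T)


# --- predict_metagenome ----------------------------------------------------

def test_single_taxon_full_abundance():
    rel = pd.DataFrame({"S1": [1.0]}, index=["TA"])
    genome = _genome({"TA": {"K00001": 3.0}})
    kt, contrib = predict_metagenome(rel, genome)
    assert kt.loc["K00001", "S1"] == pytest.approx(3.0)


def test_zero_copies_give_zero_tables():
    rel = pd.DataFrame({"S1": [0.4, 0.6]}, index=["TA", "TB"])
    genome = _genome({"TA": {"K00001": 0.0}, "TB": {"K00001": 0.0}})
    kt, contrib = predict_metagenome(rel, genome)
    assert (kt.to_numpy() == 0).all()
    assert contrib.empty


def test_three_taxon_product_sum():
    rel = pd.DataFrame({"S1": [0.5, 0.3, 0.2]}, index=["TA", "TB", "TC"])
    genome = _genome({"TA": {"K00001": 2.0}, "TB": {"K00001": 1.0},
                      "TC": {"K00001": 0.0}})
    kt, contrib = predict_metagenome(rel, genome)
    assert kt.loc["K00001", "S1"] == pytest.approx(1.3)
    by_taxon = contrib.set_index("taxon_id")["contributed_count"]
    assert by_taxon["TA"] == pytest.approx(1.0)
    assert by_taxon["TB"] == pytest.approx(0.3)
    assert "TC" not in by_taxon.index  # zero contributions are not emitted


def test_missing_taxon_named_in_error():
    rel = pd.DataFrame({"S1": [1.0]}, index=["ghost"])
    genome = _genome({"TA": {"K00001": 1.0}})
    with pytest.raises(ValueError, match="ghost"):
        predict_metagenome(rel, genome)


def test_ko_table_equals_contrib_column_sums(small_dataset):
    from indigoferm import relative_abundance
    rel = relative_abundance(small_dataset.feature_table)
    kt, contrib = predict_metagenome(rel, small_dataset.genome_content)
    sums = contrib.groupby(["ko_id", "sample_id"])["contributed_count"].sum()
    for (ko, sample), v in sums.items():
        assert kt.loc[ko, sample] == pytest.approx(v, abs=1e-9)


# --- subpathway aggregation and ratio screen -------------------------------

def test_identity_and_multimapped_aggregation():
    kt = pd.DataFrame({"S1": [5.0, 2.0]}, index=["K00001", "K00002"])
    pmap = PathwayMap(ko_to_subpathways={"K00001": {"PTS", "Starch"},
                                         "K00002": {"Starch"}})
    out = aggregate_subpathways(kt, pmap)
    assert out.loc["PTS", "S1"] == pytest.approx(5.0)    # full count to each
    assert out.loc["Starch", "S1"] == pytest.approx(7.0)


def test_unmapped_kos_pool_into_unclassified():
    kt = pd.DataFrame({"S1": [1.0, 9.0]}, index=["K00001", "K99999"])
    pmap = PathwayMap(ko_to_subpathways={"K00001": {"PTS"}})
    out = aggregate_subpathways(kt, pmap)
    assert out.loc["unclassified", "S1"] == pytest.approx(9.0)


def test_four_ko_two_subpathway_totals():
    kt = pd.DataFrame({"S1": [1.0, 2.0, 3.0, 4.0]},
                      index=["K00001", "K00002", "K00003", "K00004"])
    pmap = PathwayMap(ko_to_subpathways={
        "K00001": {"A"}, "K00002": {"A"}, "K00003": {"B"}, "K00004": {"B"}})
    out = aggregate_subpathways(kt, pmap)
    assert out.loc["A", "S1"] == pytest.approx(3.0)
    assert out.loc["B", "S1"] == pytest.approx(7.0)


def test_ratio_screen_boundary_strictly_greater():
    a = pd.Series({"p1": 2.0, "p2": 1.05, "p3": 1.051, "p4": 0.9, "p5": 3.0})
    b = pd.Series({"p1": 1.0, "p2": 1.0, "p3": 1.0, "p4": 1.0, "p5": 0.0})
    out, undefined = pathway_ratio_screen(a, b, min_ratio=1.05)
    assert list(out["subpathway"]) == ["p1", "p3"]       # sorted descending
    assert out["ratio"].tolist() == pytest.approx([2.0, 1.051])
    assert undefined == ["p5"]


def test_equal_columns_yield_no_hits():
    a = pd.Series({"p1": 3.0, "p2": 0.5})
    out, undefined = pathway_ratio_screen(a, a.copy(), min_ratio=1.05)
    assert out.empty and undefined == []


# --- taxon contribution shares ---------------------------------------------

def _contrib(rows):
    return pd.DataFrame(rows, columns=["sample_id", "ko_id", "taxon_id",
                                       "taxon_abundance", "copy_number",
                                       "contributed_count"])


def test_contribution_shares():
    pmap = PathwayMap(ko_to_subpathways={"K00001": {"PTS"}, "K00002": {"PTS"}})
    contrib = _contrib([
        ("S1", "K00001", "TA", 0.5, 4, 2.0),
        ("S1", "K00001", "TB", 0.5, 1, 0.5),
        ("S1", "K00002", "TA", 0.5, 2, 1.0),
        ("S1", "K00002", "TC", 0.2, 2.5, 0.5),
    ])
    shares = taxon_contribution_share(contrib, "PTS", pmap, "S1")
    assert shares.sum() == pytest.approx(1.0, abs=1e-9)
    assert shares["TA"] == pytest.approx(3.0 / 4.0)
    two = taxon_contribution_share(
        _contrib([("S1", "K00001", "TA", 1, 3, 3.0),
                  ("S1", "K00001", "TB", 1, 1, 1.0)]),
        "PTS", PathwayMap(ko_to_subpathways={"K00001": {"PTS"}}), "S1")
    assert two.tolist() == pytest.approx([0.75, 0.25])


def test_zero_total_rejected():
    pmap = PathwayMap(ko_to_subpathways={"K00001": {"PTS"}})
    contrib = _contrib([("S1", "K00002", "TA", 1, 1, 1.0)])
    with pytest.raises(ValueError):
        taxon_contribution_share(contrib, "PTS", pmap, "S1")


# --- KO-phenotype correlation ----------------------------------------------

def _dye(frames):
    return pd.DataFrame(frames).set_index("sample_id")


def test_proportional_changes_give_r_one():
    samples = [f"S{i}" for i in range(5)]
    intens = np.array([10.0, 14.0, 13.0, 20.0, 26.0])
    ko = 0.001 * intens + 0.05  # diffs exactly proportional
    kt = pd.DataFrame({s: [ko[i], 1.0 - ko[i]] for i, s in enumerate(samples)},
                      index=["K00001", "K00002"])
    dye = _dye({"sample_id": samples, "batch_id": ["B1"] * 5,
                "day": range(5), "intensity": intens})
    hits, r = ko_phenotype_correlation(kt, dye, min_r=0.69, normalize=False)
    assert r["K00001"] == pytest.approx(1.0, abs=1e-9)
    assert "K00001" in {h.ko_id for h in hits}


def test_constant_ko_skipped():
    samples = [f"S{i}" for i in range(4)]
    kt = pd.DataFrame({s: [2.0, float(i)] for i, s in enumerate(samples)},
                      index=["Kconst", "Kvar"])
    dye = _dye({"sample_id": samples, "batch_id": ["B1"] * 4,
                "day": range(4), "intensity": [1.0, 2.0, 4.0, 8.0]})
    hits, r = ko_phenotype_correlation(kt, dye, min_r=0.69, normalize=False)
    assert "Kconst" not in r.index


def test_two_batch_difference_pairs_match_brute_force():
    """Differences are formed within batches and pooled across them."""
    samples = ["B1D1", "B1D2", "B1D3", "B2D1", "B2D2", "B2D3"]
    x = np.array([0.1, 0.4, 0.2, 0.5, 0.3, 0.9])
    intens = np.array([10.0, 30.0, 18.0, 22.0, 11.0, 40.0])
    kt = pd.DataFrame({s: [x[i]] for i, s in enumerate(samples)}, index=["K00001"])
    dye = _dye({"sample_id": samples, "batch_id": ["B1"] * 3 + ["B2"] * 3,
                "day": [1, 2, 3] * 2, "intensity": intens})
    _, r = ko_phenotype_correlation(kt, dye, min_r=0.99, normalize=False)
    dx = np.array([0.3, -0.2, -0.2, 0.6])     # hand-built within-batch diffs
    dy = np.array([20.0, -12.0, -11.0, 29.0])
    expect = np.corrcoef(dx, dy)[0, 1]
    assert r["K00001"] == pytest.approx(expect, abs=1e-12)


def test_level_mode_correlates_raw_values():
    samples = [f"S{i}" for i in range(4)]
    vals = np.array([1.0, 2.0, 3.0, 4.0])
    kt = pd.DataFrame({s: [vals[i]] for i, s in enumerate(samples)}, index=["K00001"])
    dye = _dye({"sample_id": samples, "batch_id": ["B1"] * 4,
                "day": range(4), "intensity": vals * 2 + 1})
    _, r = ko_phenotype_correlation(kt, dye, mode="level", normalize=False)
    assert r["K00001"] == pytest.approx(1.0)


def test_lowering_threshold_never_removes_hits(small_dataset):
    from indigoferm import relative_abundance
    rel = relative_abundance(small_dataset.feature_table)
    kt, _ = predict_metagenome(rel, small_dataset.genome_content)
    hits_hi, _ = ko_phenotype_correlation(kt, small_dataset.dye_series, min_r=0.8)
    hits_lo, _ = ko_phenotype_correlation(kt, small_dataset.dye_series, min_r=0.5)
    assert {h.ko_id for h in hits_hi} <= {h.ko_id for h in hits_lo}


def test_threshold_boundary_inclusive():
    """A KO with r exactly at the threshold is retained (>= rule)."""
    samples = [f"S{i}" for i in range(4)]
    vals = [0.0, 1.0, 3.0, 6.0]
    kt = pd.DataFrame({s: [vals[i]] for i, s in enumerate(samples)}, index=["K00001"])
    dye = _dye({"sample_id": samples, "batch_id": ["B1"] * 4,
                "day": range(4), "intensity": [v * 2 for v in vals]})
    hits, r = ko_phenotype_correlation(kt, dye, min_r=1.0, normalize=False)
    assert r["K00001"] == pytest.approx(1.0)
    assert [h.ko_id for h in hits] == ["K00001"]


# --- oxidoreductase filter -------------------------------------------------

def _ann(rows):
    return pd.DataFrame.from_dict(rows, orient="index")


def test_filter_keeps_nadp_dependent_ec1():
    ann = _ann({
        "K00001": {"ec_numbers": "1.1.1.2", "nadp_dependent": True},
        "K00002": {"ec_numbers": "2.7.1.199", "nadp_dependent": True},
        "K00003": {"ec_numbers": "1.6.1.2;7.1.1.1", "nadp_dependent": True},
        "K00004": {"ec_numbers": "1.1.3.2", "nadp_dependent": False},
        "K00005": {"ec_numbers": "", "nadp_dependent": False},
    })
    hits = [CorrelationHit(k, 0.7 + i / 100, 10) for i, k in enumerate(ann.index)]
    hits.append(CorrelationHit("K99999", 0.9, 10))  # not annotated
    kept, unannotated = filter_oxidoreductases(hits, ann)
    assert [h.ko_id for h in kept] == ["K00001", "K00003"]  # order preserved
    assert [h.ko_id for h in unannotated] == ["K99999"]


# --- contribution day ratios -----------------------------------------------

def _ratio_contrib():
    return _contrib([
        ("D2", "K00001", "TA", 0.1, 10, 10.0),
        ("D3", "K00001", "TA", 0.2, 10, 20.0),
        ("D2", "K00002", "TA", 0.0, 5, 0.0),
        ("D3", "K00002", "TA", 0.1, 5, 5.0),
        ("D2", "K00003", "TA", 0.1, 7, 7.0),
        ("D3", "K00003", "TA", 0.1, 7, 7.0),
    ])


def test_day_ratio_examples():
    c = _ratio_contrib()
    assert contribution_day_ratio(c, "K00001", "TA", "D2", "D3") == pytest.approx(2.0)
    assert math.isinf(contribution_day_ratio(c, "K00002", "TA", "D2", "D3"))
    assert contribution_day_ratio(c, "K00003", "TA", "D2", "D3") == pytest.approx(1.0)


def test_day_ratio_unknowns_rejected():
    c = _ratio_contrib()
    with pytest.raises(ValueError):
        contribution_day_ratio(c, "K77777", "TA", "D2", "D3")
    with pytest.raises(ValueError):
        contribution_day_ratio(c, "K00001", "nobody", "D2", "D3")
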