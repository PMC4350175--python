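"""Tests for trajectory assembly and its summary statistics."""

import numpy as np
import pandas as pd
import pytest

from chemosweep.trajdyn import (
    build_table,
    classify_all,
    classify_mutation,
    coding_effect_summary,
    gene_frequency_sum,
    gene_summary,
    load_series,
    mutational_load,
    occurrence_spectrum,
    spectrum_summary,
)

from conftest import DAYS, make_table


def meta_frame(ids, **overrides):
    base = {
        "position": 1, "ref": "A", "alt": "G", "mut_class": "SNP",
        "gene": "g", "effect": "nonsynonymous", "role": "passenger",
    }
    rows = []
    for i, mid in enumerate(ids):
        row = dict(base)
        for k, v in overrides.items():
            row[k] = v[i] if isinstance(v, (list, tuple)) else v
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(ids, name="mutation_id"))


class TestBuildTable:
    def test_no_calls_gives_all_zero(self):
        meta = meta_frame(["a", "b"])
        calls = pd.DataFrame(columns=["mutation_id", "sample_day", "frequency", "passed"])
        table = build_table(calls, meta, DAYS)
        assert (table.freqs == 0).all().all()

    def test_single_call_single_cell(self):
        meta = meta_frame(["a"])
        calls = pd.DataFrame([{"mutation_id": "a", "sample_day": 7.0,
                               "frequency": 0.25, "passed": True}])
        table = build_table(calls, meta, DAYS)
        assert table.freqs.at["a", 7.0] == 0.25
        assert table.freqs.drop(columns=7.0).loc["a"].sum() == 0

    def test_unknown_mutation_rejected_with_identifier(self):
        meta = meta_frame(["a"])
        calls = pd.DataFrame([{"mutation_id": "ghost", "sample_day": 7.0,
                               "frequency": 0.2, "passed": True}])
        with pytest.raises(KeyError, match="ghost"):
            build_table(calls, meta, DAYS)

    def test_day_outside_grid_rejected(self):
        meta = meta_frame(["a"])
        calls = pd.DataFrame([{"mutation_id": "a", "sample_day": 99.0,
                               "frequency": 0.2, "passed": True}])
        with pytest.raises(ValueError):
            build_table(calls, meta, DAYS)


class TestOccurrenceSpectrum:
    def test_all_zero_table_gives_empty_histogram(self):
        table = make_table({"a": ({}, [0.0] * 11)})
        assert len(occurrence_spectrum(table)) == 0

    def test_bins_sum_to_detected_mutations(self):
        table = make_table({
            "a": ({}, [0.1] + [0.0] * 10),
            "b": ({}, [0.1, 0.2, 0.3] + [0.0] * 8),
            "c": ({}, [0.0] * 11),
        })
        spec = occurrence_spectrum(table)
        assert spec.sum() == 2
        assert spec[1] == 1 and spec[3] == 1

    def test_planted_singleton_fraction_recovered(self):
        rows = {}
        for i in range(80):
            rows[f"s{i:02d}"] = ({}, [0.05] + [0.0] * 10)
        for i in range(20):
            rows[f"r{i:02d}"] = ({}, [0.05, 0.05] + [0.0] * 9)
        summary = spectrum_summary(occurrence_spectrum(make_table(rows)))
        assert summary["n_singleton"] == 80 and summary["pct_singleton"] == 80

    def test_percentages_round_to_integers(self):
        spec = pd.Series({1: 2366, 2: 200, 3: 143}, name="n_mutations")
        s = spectrum_summary(spec)
        assert s["total"] == 2709
        assert s["pct_singleton"] == round(100 * 2366 / 2709)

    def test_effect_percentages(self):
        s = coding_effect_summary(64, 27, 9)
        assert (s["pct_nonsynonymous"], s["pct_synonymous"], s["pct_noncoding"]) == (64, 27, 9)


class TestClassifyMutation:
    @pytest.mark.parametrize(
        "freqs,expected",
        [
            ([0.0] * 11, "undetected"),
            ([0.0, 0.02] + [0.0] * 9, "singleton"),
            ([0.1, 0.1] + [0.0] * 9, "recurrent"),
            ([0.1, 0.1, 0.1] + [0.0] * 8, "repeated"),
            ([0.05] * 11, "persistent"),
        ],
    )
    def test_classes(self, freqs, expected):
        assert classify_mutation(pd.Series(freqs, index=DAYS)) == expected

    def test_classes_nested_and_exhaustive(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            traj = pd.Series(rng.random(11) * (rng.random(11) < 0.4), index=DAYS)
            cls = classify_mutation(traj)
            n = int((traj > 0).sum())
            assert cls in ("undetected", "singleton", "recurrent", "repeated", "persistent")
            if cls == "persistent":
                assert n == 11
            if cls in ("repeated", "persistent"):
                assert n >= 3
            if cls in ("recurrent", "repeated", "persistent"):
                assert n >= 2

    def test_classify_all_matches_rowwise(self):
        table = make_table({
            "a": ({}, [0.1] + [0.0] * 10),
            "b": ({}, [0.1] * 11),
        })
        out = classify_all(table)
        assert out["a"] == "singleton" and out["b"] == "persistent"


class TestMutationalLoad:
    def test_all_zero_day(self):
        table = make_table({"a": ({}, [0.1] + [0.0] * 10)})
        assert mutational_load(table, 60.0) == {
            "SNP": 0, "S-indel": 0, "L-indel": 0, "duplication": 0}

    def test_counts_split_by_class_and_sum(self):
        table = make_table({
            "a": ({"mut_class": "SNP"}, [0.1] + [0.0] * 10),
            "b": ({"mut_class": "S-indel"}, [0.2] + [0.0] * 10),
            "c": ({"mut_class": "SNP"}, [0.0] * 11),
        })
        load = mutational_load(table, 5.0)
        assert load == {"SNP": 1, "S-indel": 1, "L-indel": 0, "duplication": 0}
        assert sum(load.values()) == int((table.freqs[5.0] > 0).sum())

    def test_unknown_day_rejected(self):
        table = make_table({"a": ({}, [0.1] + [0.0] * 10)})
        with pytest.raises(ValueError):
            mutational_load(table, 61.0)

    def test_load_series_covers_all_days(self):
        table = make_table({"a": ({}, [0.1] * 11)})
        series = load_series(table)
        assert list(series.index) == DAYS
        assert (series["total"] == 1).all()


class TestGeneSummary:
    def test_single_persistent_allele_row(self):
        """One allele in 5 samples peaking at 0.95: the late hard-sweep
        gene pattern."""
        traj = [0.0] * 6 + [0.01, 0.2, 0.5, 0.9, 0.95]
        table = make_table({"a": ({"gene": "sdhC", "effect": "nonsynonymous"}, traj)})
        row = gene_summary(table).iloc[0]
        assert (row["gene"], row["n_samples_present"], row["n_alleles"]) == ("sdhC", 5, 1)
        assert row["peak_freq"] == pytest.approx(0.95)

    def test_peak_is_max_of_daily_sums(self):
        table = make_table({
            "a": ({"gene": "g", "effect": "nonsynonymous"}, [0.4, 0.3, 0.1] + [0.0] * 8),
            "b": ({"gene": "g", "effect": "nonsynonymous"}, [0.3, 0.35, 0.1] + [0.0] * 8),
        })
        row = gene_summary(table).iloc[0]
        # day sums: 0.7, 0.65, 0.2 -> peak 0.7 exceeds both allele maxima
        assert row["peak_freq"] == pytest.approx(0.7)
        assert row["n_alleles"] == 2

    def test_linked_alleles_of_two_genes_have_equal_peaks(self):
        traj = [0.0, 0.1, 0.4, 0.6] + [0.0] * 7
        table = make_table({
            "a": ({"gene": "g1", "effect": "nonsynonymous"}, traj),
            "b": ({"gene": "g2", "effect": "nonsynonymous"}, traj),
        })
        out = gene_summary(table)
        assert out["peak_freq"].nunique() == 1

    def test_requires_repeated_nonsynonymous_allele(self):
        table = make_table({
            "a": ({"gene": "g1", "effect": "synonymous"}, [0.2] * 11),
            "b": ({"gene": "g2", "effect": "nonsynonymous"}, [0.2, 0.2] + [0.0] * 9),
        })
        assert len(gene_summary(table)) == 0

    def test_sorted_by_peak_descending(self):
        table = make_table({
            "a": ({"gene": "lo", "effect": "nonsynonymous"}, [0.1] * 11),
            "b": ({"gene": "hi", "effect": "nonsynonymous"}, [0.8] * 11),
        })
        assert list(gene_summary(table)["gene"]) == ["hi", "lo"]


class TestGeneFrequencySum:
    def test_unknown_gene_rejected(self):
        table = make_table({"a": ({"gene": "g"}, [0.1] * 11)})
        with pytest.raises(KeyError):
            gene_frequency_sum(table, "nope")

    def test_single_allele_identity(self):
        traj = [0.1, 0.2, 0.3] + [0.0] * 8
        table = make_table({"a": ({"gene": "g", "effect": "nonsynonymous"}, traj)})
        out = gene_frequency_sum(table, "g")
        assert list(out) == pytest.approx(traj)

    def test_sum_capped_at_one_with_warning(self, caplog):
        table = make_table({
            "a": ({"gene": "g", "effect": "nonsynonymous"}, [0.7] * 11),
            "b": ({"gene": "g", "effect": "nonsynonymous"}, [0.6] * 11),
        })
        with caplog.at_level("WARNING", logger="chemosweep.trajdyn"):
            out = gene_frequency_sum(table, "g")
        assert (out <= 1.0).all()
        assert any("exceeds 1" in r.message for r in caplog.records)

    def test_synonymous_alleles_excluded(self):
        table = make_table({
            "a": ({"gene": "g", "effect": "synonymous"}, [0.5] * 11),
            "b": ({"gene": "g", "effect": "nonsynonymous"}, [0.2] * 11),
        })
        assert (gene_frequency_sum(table, "g") == 0.2).all()
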