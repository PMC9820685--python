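"""Context-score ingestion and pseudo-logFC target-gene scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mirsig
from mirsig.errors import DomainError, FormatError
from mirsig.targets import (
    ScoringConfig,
    TargetInteraction,
    interactions_frame,
)

SIG = {"miR-9-5p": "up", "miR-124-3p": "up", "miR-150-5p": "down",
       "miR-142-3p": "down"}


def accumulation_oracle(interactions, direction_map, threshold):
    """Independent single-pass accumulation of events, links and sums."""
    acc = {}
    links = {}
    for i in interactions:
        if i.mirna not in direction_map:
            continue
        g = direction_map[i.mirna]
        d = acc.setdefault(
            i.gene_symbol,
            {"n_events_up": 0, "n_events_down": 0, "sum_up": 0.0, "sum_down": 0.0},
        )
        d[f"n_events_{g}"] += 1
        d[f"sum_{g}"] += abs(i.context_score)
        links.setdefault(i.gene_symbol, {"up": set(), "down": set()})[g].add(i.mirna)
    out = {}
    for gene, d in acc.items():
        total = d["sum_up"] + d["sum_down"]
        if total < threshold:
            continue
        out[gene] = {
            **d,
            "n_links_up": len(links[gene]["up"]),
            "n_links_down": len(links[gene]["down"]),
            "cumulative_score": total,
            "pseudo_logfc": d["sum_down"] - d["sum_up"],  # simple mode
        }
    return out


class TestReadTargetscan:
    def _write(self, tmp_path, rows, header="Gene Symbol\tmiRNA\tcontext++ score"):
        p = tmp_path / "targets.tsv"
        p.write_text(header + "\n" + "\n".join(rows) + "\n")
        return p

    def test_canonical_parse(self, tmp_path):
        p = self._write(tmp_path, [
            "LCOR\tmiR-9-5p\t-0.21",
            "TP53\tmiR-150-5p\t-0.10",
            "TP53\tmiR-142-3p\t-0.05",
        ])
        parsed = mirsig.read_targetscan(p)
        assert len(parsed.interactions) == 3 and parsed.n_skipped == 0

    def test_null_score_skipped_and_counted(self, tmp_path):
        p = self._write(tmp_path, [
            "LCOR\tmiR-9-5p\t-0.21",
            "TP53\tmiR-150-5p\tNULL",
        ])
        parsed = mirsig.read_targetscan(p)
        assert len(parsed.interactions) == 1 and parsed.n_skipped == 1

    def test_sign_preserved(self, tmp_path):
        p = self._write(tmp_path, ["LCOR\tmiR-9-5p\t-0.21"])
        assert mirsig.read_targetscan(p).interactions[0].context_score == -0.21

    def test_missing_column_is_format_error(self, tmp_path):
        p = self._write(tmp_path, ["LCOR\t-0.21"], header="Gene Symbol\tscorez")
        with pytest.raises(FormatError):
            mirsig.read_targetscan(p)

    def test_column_aliases(self, tmp_path):
        p = self._write(
            tmp_path, ["LCOR\tmiR-9-5p\t-0.3"], header="gene\tmir\tcs"
        )
        parsed = mirsig.read_targetscan(
            p,
            column_aliases={
                "gene_symbol": ("gene",), "mirna": ("mir",),
                "context_score": ("cs",),
            },
        )
        assert parsed.interactions[0].gene_symbol == "LCOR"


class TestSummarize:
    def test_single_up_event(self):
        """One event from an up-miRNA: targets predicted down in metastasis."""
        inter = [TargetInteraction("miR-9-5p", "GENE1", -0.2)]
        out = mirsig.summarize_gene_targets(inter, SIG, ScoringConfig())
        assert out.loc["GENE1", "pseudo_logfc"] == pytest.approx(-0.2)
        assert out.loc["GENE1", "predicted_direction"] == "down_in_bm"

    def test_symmetric_cancellation(self):
        inter = [
            TargetInteraction("miR-9-5p", "G", -0.3),
            TargetInteraction("miR-150-5p", "G", -0.3),
        ]
        out = mirsig.summarize_gene_targets(inter, SIG, ScoringConfig())
        assert out.loc["G", "pseudo_logfc"] == pytest.approx(0.0)
        assert out.loc["G", "predicted_direction"] == "neutral"

    def test_matches_accumulation_oracle_on_random_fixtures(self):
        sig = mirsig.default_signature()
        dmap = sig.direction_map()
        for seed in range(200):
            fx = mirsig.make_target_fixture(sig, n_genes=6, seed=seed)
            out = mirsig.summarize_gene_targets(
                fx.interactions, dmap, ScoringConfig(cumulative_threshold=0.01)
            )
            oracle = accumulation_oracle(fx.interactions, dmap, 0.01)
            assert set(out.index) == set(oracle)
            for gene, exp in oracle.items():
                row = out.loc[gene]
                for key, val in exp.items():
                    assert row[key] == pytest.approx(val), (gene, key)

    def test_fixture_truth_matches(self):
        """Generation-time bookkeeping agrees with the summarizer."""
        sig = mirsig.default_signature()
        fx = mirsig.make_target_fixture(sig, n_genes=10, seed=3)
        out = mirsig.summarize_gene_targets(
            fx.interactions, sig.direction_map(), ScoringConfig(cumulative_threshold=0.0)
        )
        for gene, exp in fx.expected.iterrows():
            for col in ("n_events_up", "n_events_down", "n_links_up",
                        "n_links_down"):
                assert out.loc[gene, col] == exp[col]
            assert out.loc[gene, "sum_up"] == pytest.approx(exp["sum_up"])
            assert out.loc[gene, "sum_down"] == pytest.approx(exp["sum_down"])

    def test_non_signature_mirnas_ignored(self):
        inter = [
            TargetInteraction("miR-9-5p", "G", -0.2),
            TargetInteraction("miR-unrelated", "G", -0.9),
        ]
        out = mirsig.summarize_gene_targets(inter, SIG, ScoringConfig())
        assert out.loc["G", "cumulative_score"] == pytest.approx(0.2)

    def test_threshold_drops_genes(self):
        inter = [TargetInteraction("miR-9-5p", "G", -0.005)]
        out = mirsig.summarize_gene_targets(
            inter, SIG, ScoringConfig(cumulative_threshold=0.01)
        )
        assert out.empty

    def test_empty_signature_rejected(self):
        with pytest.raises(DomainError):
            mirsig.summarize_gene_targets(
                [TargetInteraction("m", "g", -0.1)], {}, ScoringConfig()
            )

    def test_group_scaled_weights(self):
        """w_D = N_D / (N_up + N_down) over retained genes."""
        inter = [
            TargetInteraction("miR-9-5p", "A", -0.4),
            TargetInteraction("miR-9-5p", "A", -0.2),
            TargetInteraction("miR-150-5p", "A", -0.3),
            TargetInteraction("miR-150-5p", "B", -0.5),
        ]
        out = mirsig.summarize_gene_targets(
            inter, SIG, ScoringConfig(weighting_mode="group_scaled")
        )
        w_up, w_down = 2 / 4, 2 / 4
        assert out.loc["A", "pseudo_logfc"] == pytest.approx(
            w_down * 0.3 - w_up * 0.6
        )
        assert out.loc["B", "pseudo_logfc"] == pytest.approx(w_down * 0.5)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        scores_up=st.lists(
            st.floats(min_value=-0.6, max_value=-0.011), min_size=0, max_size=5
        ),
        scores_down=st.lists(
            st.floats(min_value=-0.6, max_value=-0.011), min_size=0, max_size=5
        ),
        mode=st.sampled_from(["simple", "group_scaled"]),
    )
    def test_direction_law(self, scores_up, scores_down, mode):
        """Up-only targets never score positive; down-only never negative."""
        inter = [TargetInteraction("miR-9-5p", "GU", s) for s in scores_up]
        inter += [TargetInteraction("miR-150-5p", "GD", s) for s in scores_down]
        if not inter:
            return
        out = mirsig.summarize_gene_targets(
            inter, SIG, ScoringConfig(weighting_mode=mode)
        )
        if "GU" in out.index:
            assert out.loc["GU", "pseudo_logfc"] <= 0
        if "GD" in out.index:
            assert out.loc["GD", "pseudo_logfc"] >= 0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        s_u=st.floats(min_value=0.02, max_value=2.0),
        s_d=st.floats(min_value=0.02, max_value=2.0),
    )
    def test_mixed_attenuation_law(self, s_u, s_d):
        """A gene hit by both groups never outranks the same total score
        concentrated in one direction (simple mode)."""
        mixed = [
            TargetInteraction("miR-9-5p", "MIX", -s_u),
            TargetInteraction("miR-150-5p", "MIX", -s_d),
        ]
        pure = [TargetInteraction("miR-150-5p", "PURE", -max(s_u, s_d))]
        out = mirsig.summarize_gene_targets(
            mixed + pure, SIG, ScoringConfig(cumulative_threshold=0.0)
        )
        assert abs(out.loc["MIX", "pseudo_logfc"]) <= abs(
            out.loc["PURE", "pseudo_logfc"]
        ) + 1e-12

    def test_threshold_monotonicity(self):
        sig = mirsig.default_signature()
        fx = mirsig.make_target_fixture(sig, n_genes=20, seed=12)
        dmap = sig.direction_map()
        prev = None
        for thr in (0.0, 0.05, 0.2, 0.5, 1.0):
            genes = set(
                mirsig.summarize_gene_targets(
                    fx.interactions, dmap, ScoringConfig(cumulative_threshold=thr)
                ).index
            )
            if prev is not None:
                assert genes <= prev
            prev = genes

    def test_signature_table_input(self, default_de, default_sim):
        """A DE signature table drives scoring directly."""
        sig_table = mirsig.call_signature(default_de, default_sim.dataset.probe_info)
        fx = mirsig.make_target_fixture(mirsig.default_signature(), 5, seed=2)
        out = mirsig.summarize_gene_targets(fx.interactions, sig_table,
                                            ScoringConfig())
        assert not out.empty


class TestRankGenes:
    def _summaries(self, rows):
        df = pd.DataFrame(rows, columns=["gene", "pseudo_logfc", "cumulative_score"])
        df = df.set_index("gene")
        df["predicted_direction"] = np.where(df["pseudo_logfc"] > 0, "up_in_bm",
                                             "down_in_bm")
        return df

    def test_sorted_by_abs_value(self):
        out = mirsig.rank_genes(self._summaries(
            [("a", 0.5, 1.0), ("b", -0.9, 1.0), ("c", 0.1, 1.0)]
        ))
        assert list(out.index) == ["b", "a", "c"]

    def test_tie_break_cumulative_then_lexicographic(self):
        out = mirsig.rank_genes(self._summaries(
            [("b", 0.5, 1.0), ("a", 0.5, 1.0), ("z", -0.5, 2.0)]
        ))
        assert list(out.index) == ["z", "a", "b"]

    def test_planted_top_gene_ranks_first(self):
        sig = mirsig.default_signature()
        fx = mirsig.make_target_fixture(sig, 8, seed=21)
        dmap = sig.direction_map()
        inter = list(fx.interactions)
        inter += [TargetInteraction("miR-150-5p", "TOPGENE", -0.9)] * 6
        out = mirsig.rank_genes(
            mirsig.summarize_gene_targets(inter, dmap, ScoringConfig())
        )
        assert out.index[0] == "TOPGENE"

    def test_empty_input(self):
        empty = pd.DataFrame(columns=["pseudo_logfc", "cumulative_score"])
        assert mirsig.rank_genes(empty).empty


def test_interactions_frame_shape():
    inter = [TargetInteraction("m1", "g1", -0.1), TargetInteraction("m2", "g1", -0.2)]
    df = interactions_frame(inter)
    assert list(df.columns) == ["mirna", "gene_symbol", "context_score"]
    assert len(df) == 2
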