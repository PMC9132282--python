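import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from kinassign import naive_bayes as nb
from kinassign import pipeline as pl
from kinassign import specificity as spec
from kinassign import windows as win
from kinassign.errors import InputError, UnmodellableKinase


def make_assay(n_pos, n_neg, kinase="K1"):
    rows = []
    for i in range(n_pos + n_neg):
        rows.append({"kinase_id": kinase, "site_id": f"s{i}",
                     "phosphorylated": int(i < n_pos)})
    return pd.DataFrame(rows)


class TestPriors:
    def test_fraction_of_phosphorylated_sites(self):
        prior_fg, prior_bg = nb.estimate_priors(make_assay(100, 900), "K1")
        assert prior_fg == pytest.approx(0.1)
        assert prior_bg == pytest.approx(0.9)

    def test_all_positive_is_smoothed_off_the_boundary(self):
        prior_fg, prior_bg = nb.estimate_priors(make_assay(10, 0), "K1")
        assert 0 < prior_bg < 1e-5
        assert prior_fg + prior_bg == pytest.approx(1.0)

    def test_zero_positives_signals_unmodellable(self):
        with pytest.raises(UnmodellableKinase):
            nb.estimate_priors(make_assay(0, 10), "K1")

    def test_missing_kinase_is_input_error(self):
        with pytest.raises(InputError):
            nb.estimate_priors(make_assay(5, 5), "K2")

    def test_fold_priors_differ_from_full_data_priors(self):
        assay = make_assay(40, 60)
        full = nb.estimate_priors(assay, "K1")[0]
        fold = nb.estimate_priors(assay.iloc[:50], "K1")[0]  # unbalanced fold
        assert fold != pytest.approx(full)


class TestPosteriorFormula:
    def test_symmetric_inputs_give_half(self):
        assert nb._posterior(0.3, 0.3, 0.5, 0.5) == pytest.approx(0.5)

    def test_worked_arithmetic_point(self):
        # s_fg=0.8, s_bg=0.2, P(K)=0.1 -> 0.08/(0.08+0.18)
        assert nb._posterior(0.8, 0.2, 0.1, 0.9) == pytest.approx(
            0.3076923076923077, abs=1e-12)

    def test_zero_background_score_gives_certainty(self):
        assert nb._posterior(0.4, 0.0, 0.2, 0.8) == pytest.approx(1.0)

    def test_double_zero_defined_as_zero(self):
        assert nb._posterior(0.0, 0.0, 0.5, 0.5) == 0.0

    def test_monotone_in_foreground_score_and_prior(self):
        grid = np.linspace(0.01, 0.99, 25)
        post_s = [nb._posterior(s, 0.3, 0.2, 0.8) for s in grid]
        post_p = [nb._posterior(0.3, 0.3, p, 1 - p) for p in grid]
        assert np.all(np.diff(post_s) > 0)
        assert np.all(np.diff(post_p) > 0)


@pytest.fixture(scope="module")
def fitted_model():
    rng = np.random.default_rng(13)
    strings = []
    for i in range(400):
        s = "".join(rng.choice(list(win.AMINO_ACIDS), size=15))
        s = s[:7] + ("S" if i % 2 else "T") + s[8:]
        if i < 80:  # positives carry a planted P at +1
            s = s[:8] + "P" + s[9:]
        strings.append(s)
    windows = {f"s{i}": win.window_from_string(s)
               for i, s in enumerate(strings)}
    assay = pd.DataFrame({
        "kinase_id": "K1",
        "site_id": [f"s{i}" for i in range(400)],
        "phosphorylated": [int(i < 80) for i in range(400)],
    })
    model = nb.fit_nb_model(assay, windows, "K1")
    return model, windows


class TestNbPosterior:
    def test_matches_component_oracle_on_random_windows(self, fitted_model, rng):
        model, _ = fitted_model
        ws = [win.window_from_string(
            "".join(rng.choice(list(win.AMINO_ACIDS), size=15)))
            for _ in range(1000)]
        enc = win.encode_windows(ws)
        got = nb.nb_posterior_many(model, enc)
        bg_scoring = model.bg_pfm.with_column_weights(
            model.fg_pfm.column_weights)
        for i in (0, 17, 256, 999):
            s_fg = model.fg_pfm.score_normalized(ws[i])
            s_bg = bg_scoring.score_normalized(ws[i])
            num = s_fg * model.prior_fg
            expected = num / (num + s_bg * model.prior_bg) if num + s_bg * model.prior_bg else 0.0
            assert got[i] == pytest.approx(expected, abs=1e-9)
            assert nb.nb_posterior(model, ws[i]) == pytest.approx(expected, abs=1e-9)
        assert np.all((got >= 0) & (got <= 1))

    def test_planted_motif_raises_posterior(self, fitted_model):
        model, _ = fitted_model
        matched = win.window_from_string("AAAAAAA" + "SP" + "AAAAAA")
        unmatched = win.window_from_string("AAAAAAA" + "SA" + "AAAAAA")
        assert nb.nb_posterior(model, matched) > nb.nb_posterior(model, unmatched)


class TestBernoulli:
    def test_laplace_smoothed_fraction(self):
        assay = make_assay(8, 12)
        feats = pd.DataFrame(
            {"interactor": [True] * 3 + [False] * 17},
            index=[f"s{i}" for i in range(20)])
        params = nb.fit_bernoulli_params(assay, "K1", feats)
        theta_fg, theta_bg = params["interactor"]
        assert theta_fg == pytest.approx((3 + 1) / (8 + 2))
        assert theta_bg == pytest.approx(1 / (12 + 2))  # never true -> floor

    def test_neutral_features_reduce_to_plain_posterior(self, fitted_model):
        model, _ = fitted_model
        model2 = nb.NaiveBayesModel(
            model.kinase_id, model.fg_pfm, model.bg_pfm,
            model.prior_fg, model.prior_bg,
            bernoulli_params={"interactor": (0.3, 0.3), "in_domain": (0.6, 0.6)})
        w = win.window_from_string("AAAAAAA" + "SP" + "AAAAAA")
        feats = {"interactor": True, "in_domain": False}
        assert nb.nb_plus_posterior(model2, w, feats) == pytest.approx(
            nb.nb_posterior(model, w), abs=1e-12)

    def test_single_feature_arithmetic_and_symmetry(self):
        # s_fg = s_bg, equal priors, one feature with theta 0.8 vs 0.2
        lr_fg, lr_bg = nb._bernoulli_ratios({"f": (0.8, 0.2)}, {"f": True})
        assert nb._posterior(0.5, 0.5, 0.5, 0.5, lr_fg, lr_bg) == pytest.approx(0.8)
        lr_fg, lr_bg = nb._bernoulli_ratios({"f": (0.8, 0.2)}, {"f": False})
        assert nb._posterior(0.5, 0.5, 0.5, 0.5, lr_fg, lr_bg) == pytest.approx(0.2)

    def test_vectorized_plus_posterior_matches_scalar(self, fitted_model):
        model, windows = fitted_model
        model2 = nb.NaiveBayesModel(
            model.kinase_id, model.fg_pfm, model.bg_pfm,
            model.prior_fg, model.prior_bg,
            bernoulli_params={"interactor": (0.7, 0.1)})
        ids = [f"s{i}" for i in range(30)]
        feats = pd.DataFrame({"interactor": [i % 3 == 0 for i in range(30)]},
                             index=ids)
        enc = win.encode_windows([windows[s] for s in ids])
        got = nb.nb_plus_posterior_many(model2, enc, feats)
        for i in (0, 7, 29):
            expected = nb.nb_plus_posterior(model2, windows[ids[i]],
                                            feats.loc[ids[i]])
            assert got[i] == pytest.approx(expected, abs=1e-12)


class TestDomainEnrichment:
    def test_universal_domain_not_enriched(self):
        domains = {f"p{i}": {"D1"} for i in range(100)}
        got = nb.domain_enrichment([f"p{i}" for i in range(10)], domains,
                                   list(domains))
        assert got == set()

    def test_enriched_domain_detected_and_matches_hypergeom(self):
        pool = [f"p{i}" for i in range(100)]
        domains = {p: set() for p in pool}
        for p in pool[:5] + pool[10:15]:
            domains[p].add("D1")
        fg = pool[:10]  # 5/10 in fg vs 5/90 in rest
        got = nb.domain_enrichment(fg, domains, pool)
        assert got == {"D1"}
        # exact one-sided tail: P(X >= 5) with M=100, n=10 draws, K=10 carriers
        p_tail = hypergeom.sf(4, 100, 10, 10)
        assert p_tail < 0.05

    def test_empty_foreground_gives_empty_set(self):
        assert nb.domain_enrichment([], {"p": {"D"}}, ["p"]) == set()

    def test_foreground_outside_pool_rejected(self):
        with pytest.raises(InputError):
            nb.domain_enrichment(["x"], {}, ["p"])


class TestSiteFeatures:
    @pytest.fixture()
    def graph(self):
        g = nx.Graph()
        # K1 - p1 (direct); K1 - p1 - p2 (two hops); p2 - p3 (three hops)
        g.add_edges_from([("K1", "p1"), ("p1", "p2"), ("p2", "p3")])
        return g

    def test_direct_and_indirect_partners(self, graph):
        assert nb.interactors_within(graph, "K1") == {"p1", "p2"}
        # independent BFS oracle
        oracle = {n for n in graph
                  if n != "K1"
                  and nx.shortest_path_length(graph, "K1", n) <= 2}
        assert nb.interactors_within(graph, "K1") == oracle

    def test_three_hops_is_not_an_interactor(self, graph):
        domains = pd.DataFrame(columns=["protein_id", "domain_id", "start", "end"])
        feats = nb.compute_site_features(
            "K1", win.Phosphosite("p3", 5, "S"), graph, domains, set(), set())
        assert feats.interactor is False

    def test_domain_interval_boundaries_inclusive(self, graph):
        domains = pd.DataFrame([
            {"protein_id": "p1", "domain_id": "D1", "start": 40, "end": 60},
        ])
        inside = nb.compute_site_features(
            "K1", win.Phosphosite("p1", 50, "S"), graph, domains, set(), set())
        assert inside.in_domain is True and inside.interactor is True
        domains2 = pd.DataFrame([
            {"protein_id": "p1", "domain_id": "D1", "start": 51, "end": 60},
        ])
        outside = nb.compute_site_features(
            "K1", win.Phosphosite("p1", 50, "S"), graph, domains2, set(), set())
        assert outside.in_domain is False

    def test_unknown_protein_defaults_all_false(self, graph):
        domains = pd.DataFrame(columns=["protein_id", "domain_id", "start", "end"])
        feats = nb.compute_site_features(
            "K1", win.Phosphosite("nowhere", 1, "S"), graph, domains,
            {"D1"}, {"D1"})
        assert not any(feats.as_dict().values())

    def test_enriched_domain_flags(self, graph):
        domains = pd.DataFrame([
            {"protein_id": "p2", "domain_id": "D9", "start": 1, "end": 5},
        ])
        feats = nb.compute_site_features(
            "K1", win.Phosphosite("p2", 10, "S"), graph, domains,
            enriched_substrate_domains={"D9"},
            enriched_interactor_domains=set())
        assert feats.domain_enriched_substrates is True
        assert feats.domain_enriched_interactors is False


class TestFitModel:
    def test_no_negatives_unmodellable(self, fitted_model):
        _, windows = fitted_model
        assay = pd.DataFrame({"kinase_id": "K1",
                              "site_id": ["s0", "s1"],
                              "phosphorylated": [1, 1]})
        with pytest.raises(UnmodellableKinase):
            nb.fit_nb_model(assay, windows, "K1")

    def test_small_kinase_flagged_but_modelled(self, fitted_model, caplog):
        _, windows = fitted_model
        assay = pd.DataFrame({
            "kinase_id": "K1",
            "site_id": [f"s{i}" for i in range(50)],
            "phosphorylated": [int(i < 5) for i in range(50)],
        })
        with caplog.at_level("WARNING"):
            model = nb.fit_nb_model(assay, windows, "K1")
        assert model.n_substrates == 5
        assert any("only 5 substrates" in r.message for r in caplog.records)
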