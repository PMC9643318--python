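import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bmrepurpose import SimulationSpec, filter_degs, tanimoto
from bmrepurpose.chem import fingerprint
from bmrepurpose.netscore import raw_score
from bmrepurpose.ranking import consensus_prior
from bmrepurpose.simulate import (
    gen_deg_table,
    gen_rankings,
    gen_response_matrix,
    gen_signatures,
    gen_smiles_library,
    gen_trajectory,
)
from bmrepurpose.sensitivity import drop_missing_drugs
from bmrepurpose.signatures import SignedGeneSet
from bmrepurpose.thermo import dccm


class TestDegGenerator:
    def test_planted_genes_survive_the_filter_exactly(self):
        spec = SimulationSpec(n_genes=100, frac_de=0.2, seed=1)
        table, truth = gen_deg_table(spec)
        assert len(truth) == 20
        assert filter_degs(table, 0.05, 1.0).genes == truth

    def test_zero_differential_fraction(self):
        spec = SimulationSpec(n_genes=50, frac_de=0.0, seed=1)
        table, truth = gen_deg_table(spec)
        assert truth == set()
        assert len(filter_degs(table, 0.05, 1.0)) == 0

    def test_deterministic_across_calls(self):
        spec = SimulationSpec(n_genes=200, frac_de=0.1, seed=9)
        t1, s1 = gen_deg_table(spec)
        t2, s2 = gen_deg_table(spec)
        pd.testing.assert_frame_equal(t1, t2)
        assert s1 == s2

    def test_weak_effect_size_rejected(self):
        with pytest.raises(ValueError, match="lfc_effect"):
            gen_deg_table(SimulationSpec(n_genes=100, frac_de=0.1, lfc_effect=0.5))


class TestRankingGenerator:
    def test_three_sources_of_fifty(self, small_spec):
        rankings, _ = gen_rankings(small_spec, cutoff=50)
        assert [len(r) for r in rankings] == [50, 50, 50]

    def test_no_noise_full_overlap_recovers_latent_order(self):
        spec = SimulationSpec(
            n_drugs=80, n_sources=3, source_overlap=1.0, rank_noise_sd=0.0, seed=5
        )
        rankings, truth = gen_rankings(spec, cutoff=50)
        assert rankings[0].drugs == rankings[1].drugs == rankings[2].drugs
        prior = consensus_prior(rankings, cutoff=50)
        assert list(prior["drug"]) == truth[:50]

    def test_consensus_correlates_with_truth_under_noise(self):
        """Moderate ranking noise still leaves a strong consensus signal."""
        rhos = []
        for rep in range(100):
            spec = SimulationSpec(
                n_drugs=60, n_sources=3, source_overlap=0.8,
                rank_noise_sd=0.5, seed=1000 + rep,
            )
            rankings, truth = gen_rankings(spec, cutoff=50)
            prior = consensus_prior(rankings, cutoff=50)
            truth_pos = {d: i for i, d in enumerate(truth)}
            got = [truth_pos[d] for d in prior["drug"]]
            rho, _ = stats.spearmanr(got, range(len(got)))
            rhos.append(rho)
        assert np.mean(rhos) > 0.8


class TestSignatureGenerator:
    DISEASE = SignedGeneSet({f"g{i}": (1 if i % 2 else -1) for i in range(200)})

    def test_full_reversal_has_no_mimic_edges(self):
        spec = SimulationSpec(n_compounds=1, reversal_strength=1.0, seed=2)
        sigs, truth = gen_signatures(spec, self.DISEASE)
        assert truth["compound001"] == 1.0
        assert raw_score(sigs[0], self.DISEASE) == 1.0

    def test_half_reversal_raw_score_near_zero(self):
        """Expectation (2*0.5 - 1) = 0: mean raw over replicates sits near 0."""
        raws = []
        for rep in range(30):
            spec = SimulationSpec(
                n_compounds=1, reversal_strength=0.5, n_shared_genes=100,
                seed=300 + rep,
            )
            sigs, _ = gen_signatures(spec, self.DISEASE)
            raws.append(raw_score(sigs[0], self.DISEASE))
        assert abs(np.mean(raws)) < 0.05
        assert np.mean([abs(r) < 0.2 for r in raws]) >= 0.9

    def test_strengths_recorded_per_compound(self):
        spec = SimulationSpec(n_compounds=3, seed=4)
        _, truth = gen_signatures(spec, self.DISEASE, strengths=[0.9, 0.4, 0.1])
        assert truth == {
            "compound001": 0.9, "compound002": 0.4, "compound003": 0.1
        }


class TestSmilesLibrary:
    def test_all_structures_parse(self):
        from rdkit import Chem

        records, _ = gen_smiles_library(10, seed=1)
        assert len(records) == 10
        assert all(Chem.MolFromSmiles(r.smiles) is not None for r in records)

    def test_planted_pair_above_redundancy_threshold(self):
        records, truth = gen_smiles_library(20, seed=1)
        fp = {r.id: fingerprint(r.smiles) for r in records}
        assert truth["pairs"], "expected at least one planted pair"
        for a, b in truth["pairs"]:
            assert tanimoto(fp[a], fp[b]) > 0.8

    def test_unrelated_scaffolds_below_point_four(self):
        records, truth = gen_smiles_library(60, seed=1)
        fp = {r.id: fingerprint(r.smiles) for r in records}
        sc = truth["scaffold"]
        # alkyl-cyclohexane scaffold (0) vs naphthalene scaffold (4)
        a_ids = [r.id for r in records if sc[r.id] == 0]
        b_ids = [r.id for r in records if sc[r.id] == 4]
        assert a_ids and b_ids
        for a in a_ids:
            for b in b_ids:
                assert tanimoto(fp[a], fp[b]) < 0.4

    def test_deterministic(self):
        r1, t1 = gen_smiles_library(15, seed=7)
        r2, t2 = gen_smiles_library(15, seed=7)
        assert [x.smiles for x in r1] == [x.smiles for x in r2]
        assert t1 == t2


class TestResponseGenerator:
    def test_no_missing_when_na_fraction_zero(self):
        spec = SimulationSpec(n_cell_lines=20, n_drugs=30, na_fraction=0.0, seed=6)
        m, _ = gen_response_matrix(spec)
        assert not m.isna().any().any()

    def test_planted_sensitive_drugs_below_threshold_everywhere(self):
        spec = SimulationSpec(n_cell_lines=20, n_drugs=30, na_fraction=0.0, seed=6)
        m, truth = gen_response_matrix(spec)
        for d in truth:
            assert (m[d] < 10.0).all()
        for d in set(m.columns) - truth:
            assert (m[d] >= 10.0).all()

    def test_high_na_drugs_are_discarded_downstream(self):
        spec = SimulationSpec(
            n_cell_lines=100, n_drugs=30, na_fraction=0.0, n_high_na_drugs=3, seed=6
        )
        m, _ = gen_response_matrix(spec)
        kept = drop_missing_drugs(m, 0.20)
        assert m.shape[1] - kept.shape[1] == 3


class TestTrajectoryGenerator:
    def test_antiphase_blocks_near_noiseless_limit(self):
        spec = SimulationSpec(
            n_particles=10, n_frames=80, noise_sd=1e-9, seed=8
        )
        traj, _, blocks = gen_trajectory(spec)
        c = dccm(traj)
        (b0, _), (b1, _) = blocks
        cross = c[np.ix_(b0, b1)]
        np.testing.assert_allclose(cross, -1.0, atol=1e-6)

    def test_deterministic(self):
        spec = SimulationSpec(n_particles=6, n_frames=20, seed=11)
        t1, ids1, _ = gen_trajectory(spec)
        t2, ids2, _ = gen_trajectory(spec)
        np.testing.assert_array_equal(t1, t2)
        assert ids1 == ids2

    def test_overlapping_blocks_rejected(self):
        spec = SimulationSpec(
            n_particles=4, block_spec=(((0, 1), 1), ((1, 2), -1)), seed=1
        )
        with pytest.raises(ValueError, match="unique"):
            gen_trajectory(spec)


def test_spec_validation():
    with pytest.raises(ValueError):
        SimulationSpec(frac_de=1.5)
    with pytest.raises(ValueError):
        SimulationSpec(n_genes=0)
    with pytest.raises(ValueError):
        SimulationSpec(n_compounds=2, reversal_strength=(0.5,))
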