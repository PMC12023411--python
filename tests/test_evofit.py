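"""Evolutionary fitness: MSA filtering, VAE training, scoring, interfaces."""

import itertools

import numpy as np
import pandas as pd
import pytest

from coldzyme import evofit
from coldzyme.evofit import MSA, VaeArch

from conftest import make_two_chain_structure


class TestMsaFilter:
    def test_gap_threshold_boundary(self):
        ok = "A" * 75 + "-" * 25
        too_gappy = "A" * 74 + "-" * 26
        msa = MSA(sequences=[ok, too_gappy], ids=["keep", "drop"])
        out = evofit.msa_filter(msa)
        assert out.ids == ["keep"]

    def test_exact_duplicates_collapse(self):
        msa = MSA(sequences=["ACDEFGHIKL", "ACDEFGHIKL", "VWYVWYVWYV"])
        out = evofit.msa_filter(msa)
        assert out.n_seq == 2

    def test_greedy_clustering_matches_brute_force(self):
        # 10 sequences of length 40 with pairwise identities straddling 95%
        rng = np.random.default_rng(8)
        base = "".join(rng.choice(list(evofit.AMINO_ACIDS), 40))
        seqs = [base]
        for k in (1, 1, 2, 2, 3, 5, 8, 12, 20):  # mutations from base
            s = list(base)
            for pos in rng.choice(40, size=k, replace=False):
                choices = [c for c in evofit.AMINO_ACIDS if c != s[pos]]
                s[pos] = rng.choice(choices)
            seqs.append("".join(s))
        msa = MSA(sequences=seqs)
        out = evofit.msa_filter(msa, max_identity=0.95)

        # brute-force greedy oracle over exhaustive pairwise identities
        def identity(a, b):
            both = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            return sum(x == y for x, y in both) / len(both)

        kept = []
        for s in seqs:
            if all(identity(s, t) < 0.95 for t in kept):
                kept.append(s)
        assert out.sequences == kept

    def test_idempotent(self):
        msa = MSA(sequences=["ACDEFGHIKL", "ACDEFGHIKV", "VWYVWYVWYV"])
        once = evofit.msa_filter(msa)
        twice = evofit.msa_filter(once)
        assert once.sequences == twice.sequences

    def test_column_order_independent(self):
        seqs = ["ACDEFGHIKL", "LKIHGFEDCA", "AAAAAAAAAA"]
        msa = MSA(sequences=seqs)
        perm = np.random.default_rng(0).permutation(10)
        permuted = MSA(sequences=["".join(s[i] for i in perm) for s in seqs])
        assert len(evofit.msa_filter(msa).sequences) == len(evofit.msa_filter(permuted).sequences)

    def test_empty_result_returned_not_raised(self):
        msa = MSA(sequences=["-" * 10, "-" * 10])
        out = evofit.msa_filter(msa)
        assert out.n_seq == 0


class TestOnehot:
    def test_round_trip(self, toy_family):
        enc = evofit.onehot_encode(toy_family)
        assert evofit.onehot_decode(enc) == toy_family.sequences

    def test_channel_sums_are_one(self, toy_family):
        enc = evofit.onehot_encode(toy_family)
        assert np.allclose(enc.sum(axis=-1), 1.0)

    def test_column_frequencies_match_counting(self, toy_family):
        enc = evofit.onehot_encode(toy_family)
        freq = enc.mean(axis=0)
        col = 0
        counts = np.zeros(21)
        for seq in toy_family.sequences:
            counts[evofit.ALPHABET.index(seq[col])] += 1
        assert np.allclose(freq[col], counts / toy_family.n_seq)

    def test_unknown_character_rejected(self):
        with pytest.raises(ValueError, match="unknown characters"):
            MSA(sequences=["ACDX"])


class TestTraining:
    def test_elbo_improves(self, trained_vae):
        _, trace = trained_vae
        assert trace[-1] > trace[0]

    def test_repeated_sequence_is_reconstructed(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        msa = MSA(sequences=[seq] * 50)
        arch = VaeArch(encoder_hidden=[16], decoder_hidden=[16], latent_dim=2,
                       epochs=400, seed=2)
        model, _ = evofit.train_vae(msa, arch)
        x = evofit.onehot_encode(MSA([seq])).reshape(1, -1)
        mu, _, _, _ = model.encode(x)
        logp, *_ = model.decode(mu)
        recon = "".join(evofit.ALPHABET[k] for k in logp[0].argmax(axis=-1))
        assert recon == seq

    def test_deterministic_replay(self, toy_family):
        arch = VaeArch(encoder_hidden=[16], decoder_hidden=[16], latent_dim=4,
                       epochs=30, seed=9)
        _, t1 = evofit.train_vae(toy_family, arch)
        _, t2 = evofit.train_vae(toy_family, arch)
        assert t1[-1] == pytest.approx(t2[-1], abs=1e-6)


class TestMutationFitness:
    def test_self_mutation_scores_zero(self, trained_vae, toy_family):
        model, _ = trained_vae
        wt = toy_family.consensus
        assert evofit.mutation_fitness(model, wt, f"{wt[0]}1{wt[0]}") == 0.0

    def test_wt_mismatch_names_observed_residue(self, trained_vae, toy_family):
        model, _ = trained_vae
        wt = toy_family.consensus
        wrong = "C" if wt[0] != "C" else "D"
        with pytest.raises(ValueError, match="has"):
            evofit.mutation_fitness(model, wt, f"{wrong}1A")

    def test_invariant_column_less_fit_than_free_column(self, trained_vae, toy_family):
        """Mutating a conserved position must cost more likelihood than a
        free position, across 20 scoring replicates."""
        model, _ = trained_vae
        wt = toy_family.consensus
        classes = toy_family.column_classes
        inv = next(i for i, c in enumerate(classes) if c == "invariant")
        free = next(i for i, c in enumerate(classes) if c == "free")

        def mut_label(col):
            aa = wt[col]
            return f"{aa}{col + 1}" + ("A" if aa != "A" else "C")

        wins = 0
        for seed in range(20):
            s_inv = evofit.mutation_fitness(model, wt, mut_label(inv), 500, seed=seed)
            s_free = evofit.mutation_fitness(model, wt, mut_label(free), 500, seed=seed)
            wins += s_inv > s_free
        assert wins >= 19

    def test_score_variance_shrinks_with_samples(self, trained_vae, toy_family):
        model, _ = trained_vae
        wt = toy_family.consensus
        col = next(i for i, c in enumerate(toy_family.column_classes) if c == "free")
        aa = wt[col]
        label = f"{aa}{col + 1}" + ("A" if aa != "A" else "C")
        small = [evofit.mutation_fitness(model, wt, label, 100, seed=s) for s in range(8)]
        large = [evofit.mutation_fitness(model, wt, label, 1600, seed=s) for s in range(8)]
        assert np.std(large) < np.std(small)

    def test_position_classes_separate_by_auc(self, trained_vae, toy_family):
        """Conserved positions systematically score less fit than free ones
        (AUC >= 0.9 at the scaled-down defaults)."""
        model, _ = trained_vae
        wt = toy_family.consensus
        classes = toy_family.column_classes
        inv_cols = [i for i, c in enumerate(classes) if c == "invariant"][:5]
        free_cols = [i for i, c in enumerate(classes) if c == "free"][:5]

        def score(col):
            aa = wt[col]
            label = f"{aa}{col + 1}" + ("A" if aa != "A" else "C")
            return evofit.mutation_fitness(model, wt, label, 500, seed=3)

        inv_scores = [score(c) for c in inv_cols]
        free_scores = [score(c) for c in free_cols]
        auc = np.mean([a > b for a, b in itertools.product(inv_scores, free_scores)])
        assert auc >= 0.9


class TestParseMutation:
    def test_parse(self):
        assert evofit.parse_mutation("V648E") == ("V", 648, "E")

    @pytest.mark.parametrize("bad", ["648E", "VE", "Z10A", "V10Z", ""])
    def test_reject(self, bad):
        with pytest.raises(ValueError):
            evofit.parse_mutation(bad)


class TestInterfaceContacts:
    def test_boundary_distances(self):
        import biotite.structure as struc

        arr = struc.AtomArray(2)
        arr.coord = np.array([[0.0, 0, 0], [5.4, 0, 0]])
        arr.chain_id = np.array(["A", "B"])
        arr.res_id = np.array([1, 1])
        arr.element = np.array(["C", "C"])
        arr.atom_name = np.array(["CA", "CA"])
        arr.res_name = np.array(["ALA", "ALA"])
        contacts, iface = evofit.interface_contacts(arr, cutoff=5.5)
        assert len(contacts) == 1
        arr.coord[1, 0] = 5.6
        contacts, _ = evofit.interface_contacts(arr, cutoff=5.5)
        assert contacts == []

    def test_matches_brute_force(self, two_chain_structure):
        contacts, iface = evofit.interface_contacts(two_chain_structure, cutoff=5.5)
        heavy = two_chain_structure[two_chain_structure.element != "H"]
        A = heavy[heavy.chain_id == "A"]
        B = heavy[heavy.chain_id == "B"]
        brute = {}
        for i in range(len(A)):
            for j in range(len(B)):
                d = float(np.linalg.norm(A.coord[i] - B.coord[j]))
                key = (int(A.res_id[i]), int(B.res_id[j]))
                brute[key] = min(brute.get(key, np.inf), d)
        expected = sorted((k[0], k[1], v) for k, v in brute.items() if v < 5.5)
        got = sorted(contacts)
        assert [(a, b) for a, b, _ in got] == [(a, b) for a, b, _ in expected]
        assert np.allclose([d for *_, d in got], [d for *_, d in expected])

    def test_hydrogens_excluded(self):
        import biotite.structure as struc

        arr = struc.AtomArray(3)
        arr.coord = np.array([[0.0, 0, 0], [10.0, 0, 0], [4.0, 0, 0]])
        arr.chain_id = np.array(["A", "B", "B"])
        arr.res_id = np.array([1, 1, 1])
        arr.element = np.array(["C", "C", "H"])  # only the H is close
        arr.atom_name = np.array(["CA", "CA", "H1"])
        arr.res_name = np.array(["ALA", "ALA", "ALA"])
        contacts, _ = evofit.interface_contacts(arr, cutoff=5.5)
        assert contacts == []

    def test_single_chain_rejected(self):
        import biotite.structure as struc

        arr = struc.AtomArray(2)
        arr.coord = np.zeros((2, 3))
        arr.chain_id = np.array(["A", "A"])
        arr.res_id = np.array([1, 2])
        arr.element = np.array(["C", "C"])
        with pytest.raises(ValueError, match="two chains"):
            evofit.interface_contacts(arr)


TABLE2 = pd.DataFrame(
    {
        "mutation": [
            "V648E", "F702L", "T742V", "T745P", "V744A", "R748E",
            "K743A", "L967S", "L740V", "P741K", "P968S",
        ],
        "score": [-2.53, -1.97, -1.08, -0.94, -0.87, -0.21, 0.47, 1.75, 2.62, 3.77, 4.16],
    }
)


class TestRanking:
    def test_top_three_candidates(self):
        interface = set(int(m[1:-1]) for m in TABLE2["mutation"])
        top = evofit.rank_interface_mutations(TABLE2, interface, top_k=3)
        assert list(top["mutation"]) == ["V648E", "F702L", "T742V"]

    def test_empty_interface_gives_empty_table(self):
        out = evofit.rank_interface_mutations(TABLE2, set())
        assert out.empty

    def test_input_order_invariant(self):
        interface = set(int(m[1:-1]) for m in TABLE2["mutation"])
        shuffled = TABLE2.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = evofit.rank_interface_mutations(TABLE2, interface)
        b = evofit.rank_interface_mutations(shuffled, interface)
        assert list(a["mutation"]) == list(b["mutation"])


class TestBuriedSurface:
    def test_distant_chains_bury_nothing(self):
        arr = make_two_chain_structure(10, seed=1, chain_offset=500.0)
        assert evofit.buried_surface_fraction(arr) == pytest.approx(0.0, abs=0.01)

    def test_touching_spheres_match_cap_geometry(self):
        import biotite.structure as struc

        # two carbon 'spheres' at closer than the sum of effective radii:
        # buried fraction = h/(2a) per the spherical-cap area, a = r_vdw + probe
        arr = struc.AtomArray(2)
        a = 1.7 + 1.4
        d = 0.8 * 2 * a
        arr.coord = np.array([[0.0, 0, 0], [d, 0, 0]])
        arr.chain_id = np.array(["A", "B"])
        arr.res_id = np.array([1, 1])
        arr.element = np.array(["C", "C"])
        arr.atom_name = np.array(["CA", "CA"])
        arr.res_name = np.array(["ALA", "ALA"])
        frac = evofit.buried_surface_fraction(arr, probe=1.4, point_number=2000)
        h = a - d / 2
        expected = 100.0 * (2 * np.pi * a * h) / (4 * np.pi * a**2)
        assert frac == pytest.approx(expected, rel=0.05)

    def test_rigid_motion_invariant(self, two_chain_structure):
        f1 = evofit.buried_surface_fraction(two_chain_structure)
        moved = two_chain_structure.copy()
        moved.coord = moved.coord + np.array([100.0, -30.0, 7.0])
        f2 = evofit.buried_surface_fraction(moved)
        assert f1 == pytest.approx(f2, abs=1e-6)
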