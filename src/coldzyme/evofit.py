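"""Evolutionary-fitness scoring of point mutations from a family MSA.

A small variational autoencoder is trained on the one-hot encoded
alignment of a protein family; the evolutionary fitness of a point
mutation is the negative difference of importance-weighted ELBO
estimates between the mutant and the wild-type sequence (lower score =
fitter, i.e. the mutant is at least as likely under the family model as
the wild type).  Interface residues of a dimer are selected by a
heavy-atom distance cutoff, and candidate mutations are ranked by score
restricted to the interface.

The VAE is a compact numpy implementation (MLP encoder/decoder, ReLU
activations, diagonal-Gaussian posterior, per-position softmax output)
trained full-batch with Adam; it is deliberately small enough to train
in seconds on synthetic families while keeping the architecture of the
scaled-up family model (configurable hidden sizes and latent dimension).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import logsumexp

import biotite.structure as struc

__all__ = [
    "AMINO_ACIDS",
    "ALPHABET",
    "MSA",
    "VaeArch",
    "VAE",
    "msa_filter",
    "onehot_encode",
    "onehot_decode",
    "train_vae",
    "sequence_elbo",
    "mutation_fitness",
    "parse_mutation",
    "interface_contacts",
    "rank_interface_mutations",
    "buried_surface_fraction",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "-"
_CHAR_INDEX = {c: i for i, c in enumerate(ALPHABET)}


@dataclass
class MSA:
    """Aligned sequences over the 20 amino acids plus gap."""

    sequences: list[str]
    ids: list[str] | None = None
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.ids is None:
            self.ids = [f"seq{i}" for i in range(len(self.sequences))]
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids must match sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("all sequences must have equal length")
        bad = set("".join(self.sequences)) - set(ALPHABET)
        if bad:
            raise ValueError(f"unknown characters in alignment: {sorted(bad)}")

    @property
    def n_seq(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


def _pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching residues over mutually non-gap columns."""
    matches = compared = 0
    for x, y in zip(a, b):
        if x != "-" and y != "-":
            compared += 1
            if x == y:
                matches += 1
    return matches / compared if compared else 0.0


def msa_filter(msa: MSA, max_gap_frac: float = 0.25, max_identity: float = 0.95) -> MSA:
    """Gap and redundancy filtering of a family alignment.

    Drops sequences with gap fraction above ``max_gap_frac``, then
    greedily removes redundancy in input order (Hobohm-1 style): a
    sequence is kept only if its identity to every already-kept sequence
    is below ``max_identity``.  Deterministic given input order; an empty
    result is returned (not raised).
    """
    L = msa.length
    kept_seqs: list[str] = []
    kept_ids: list[str] = []
    for seq, sid in zip(msa.sequences, msa.ids):
        if seq.count("-") / L > max_gap_frac:
            continue
        if any(_pairwise_identity(seq, k) >= max_identity for k in kept_seqs):
            continue
        kept_seqs.append(seq)
        kept_ids.append(sid)
    return MSA(sequences=kept_seqs, ids=kept_ids)


def onehot_encode(msa: MSA) -> np.ndarray:
    """One-hot tensor (n_seq, L, 21); the gap is its own channel."""
    out = np.zeros((msa.n_seq, msa.length, len(ALPHABET)))
    for i, seq in enumerate(msa.sequences):
        for j, c in enumerate(seq):
            out[i, j, _CHAR_INDEX[c]] = 1.0
    return out


def onehot_decode(tensor: np.ndarray) -> list[str]:
    """Inverse of :func:`onehot_encode` (argmax per position)."""
    idx = np.argmax(tensor, axis=-1)
    return ["".join(ALPHABET[k] for k in row) for row in idx]


@dataclass
class VaeArch:
    """Architecture and training schedule of the family VAE.

    The full-scale family model uses encoder hidden sizes
    [2000, 1000, 300] (decoder mirrored) and tens of thousands of
    epochs; the defaults here are the scaled-down test surface.
    """

    encoder_hidden: list[int] = field(default_factory=lambda: [64, 32])
    decoder_hidden: list[int] = field(default_factory=lambda: [32, 64])
    latent_dim: int = 8
    epochs: int = 200
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1 or self.epochs < 1:
            raise ValueError("latent_dim and epochs must be >= 1")
        if any(h < 1 for h in self.encoder_hidden + self.decoder_hidden):
            raise ValueError("hidden sizes must be >= 1")


def _relu(x):
    return np.maximum(x, 0.0)


class VAE:
    """Compact MLP variational autoencoder over one-hot alignments."""

    def __init__(self, L: int, arch: VaeArch):
        self.L = L
        self.K = len(ALPHABET)
        self.arch = arch
        rng = np.random.default_rng(arch.seed)
        d_in = L * self.K
        self.params: dict[str, np.ndarray] = {}

        def init_linear(name, din, dout):
            s = np.sqrt(2.0 / din)
            self.params[f"W_{name}"] = rng.normal(0.0, s, size=(din, dout))
            self.params[f"b_{name}"] = np.zeros(dout)

        sizes = [d_in] + list(arch.encoder_hidden)
        for i in range(len(arch.encoder_hidden)):
            init_linear(f"enc{i}", sizes[i], sizes[i + 1])
        init_linear("mu", sizes[-1], arch.latent_dim)
        init_linear("logvar", sizes[-1], arch.latent_dim)
        dsizes = [arch.latent_dim] + list(arch.decoder_hidden)
        for i in range(len(arch.decoder_hidden)):
            init_linear(f"dec{i}", dsizes[i], dsizes[i + 1])
        init_linear("out", dsizes[-1], d_in)

        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward pieces ---------------------------------------------------

    def encode(self, X: np.ndarray):
        """Posterior parameters (mu, logvar) for flattened one-hot X."""
        h = X
        cache = [("input", X)]
        for i in range(len(self.arch.encoder_hidden)):
            a = h @ self.params[f"W_enc{i}"] + self.params[f"b_enc{i}"]
            h = _relu(a)
            cache.append((f"enc{i}", (a, h)))
        mu = h @ self.params["W_mu"] + self.params["b_mu"]
        logvar = h @ self.params["W_logvar"] + self.params["b_logvar"]
        logvar = np.clip(logvar, -10.0, 10.0)
        return mu, logvar, h, cache

    def decode(self, Z: np.ndarray):
        """Per-position log-probabilities from latent samples."""
        g = Z
        cache = []
        for i in range(len(self.arch.decoder_hidden)):
            a = g @ self.params[f"W_dec{i}"] + self.params[f"b_dec{i}"]
            g = _relu(a)
            cache.append((a, g))
        logits = g @ self.params["W_out"] + self.params["b_out"]
        B = Z.shape[0]
        lg = logits.reshape(B, self.L, self.K)
        logp = lg - logsumexp(lg, axis=-1, keepdims=True)
        return logp, logits, g, cache

    def log_px_given_z(self, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
        """Reconstruction log-likelihood per sequence."""
        logp, *_ = self.decode(Z)
        return np.sum(X.reshape(Z.shape[0], self.L, self.K) * logp, axis=(1, 2))

    # -- training ---------------------------------------------------------

    def _step(self, X: np.ndarray, eps: np.ndarray) -> float:
        """One full-batch gradient step on the negative ELBO; returns ELBO/seq."""
        B = X.shape[0]
        mu, logvar, h_enc, enc_cache = self.encode(X)
        std = np.exp(0.5 * logvar)
        Z = mu + eps * std
        logp, logits, g_dec, dec_cache = self.decode(Z)

        X3 = X.reshape(B, self.L, self.K)
        recon = np.sum(X3 * logp, axis=(1, 2))
        kl = 0.5 * np.sum(np.exp(logvar) + mu**2 - 1.0 - logvar, axis=1)
        elbo = float(np.mean(recon - kl))

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}

        # loss = mean(-recon + kl); d loss/d logits = (softmax - x)/B
        d_logits = (np.exp(logp) - X3).reshape(B, self.L * self.K) / B

        # backprop decoder
        grads["W_out"] = g_dec.T @ d_logits
        grads["b_out"] = d_logits.sum(axis=0)
        d = d_logits @ self.params["W_out"].T
        for i in reversed(range(len(self.arch.decoder_hidden))):
            a, g_prev_out = dec_cache[i]
            d = d * (a > 0)
            g_prev = Z if i == 0 else dec_cache[i - 1][1]
            grads[f"W_dec{i}"] = g_prev.T @ d
            grads[f"b_dec{i}"] = d.sum(axis=0)
            d = d @ self.params[f"W_dec{i}"].T
        dZ = d

        # z = mu + eps*std; KL gradients
        d_mu = dZ + mu / B
        d_logvar = dZ * eps * 0.5 * std + 0.5 * (np.exp(logvar) - 1.0) / B

        grads["W_mu"] = h_enc.T @ d_mu
        grads["b_mu"] = d_mu.sum(axis=0)
        grads["W_logvar"] = h_enc.T @ d_logvar
        grads["b_logvar"] = d_logvar.sum(axis=0)
        d = d_mu @ self.params["W_mu"].T + d_logvar @ self.params["W_logvar"].T
        for i in reversed(range(len(self.arch.encoder_hidden))):
            a, _h = enc_cache[i + 1][1]
            d = d * (a > 0)
            h_prev = X if i == 0 else enc_cache[i][1][1]
            grads[f"W_enc{i}"] = h_prev.T @ d
            grads[f"b_enc{i}"] = d.sum(axis=0)
            d = d @ self.params[f"W_enc{i}"].T

        self._adam(grads)
        return elbo

    def _adam(self, grads, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        lr = self.arch.learning_rate
        t = self._adam_t
        for k, g in grads.items():
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g**2
            mhat = self._adam_m[k] / (1 - beta1**t)
            vhat = self._adam_v[k] / (1 - beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)


def train_vae(msa: MSA, arch: VaeArch | None = None) -> tuple[VAE, np.ndarray]:
    """Train the family VAE; returns the model and the per-epoch ELBO trace.

    Full-batch stochastic gradient ascent on the evidence lower bound
    (reconstruction + KL to a standard-normal prior) with one
    reparameterisation draw per epoch; reproducible given the seed.
    Divergence (non-finite loss) aborts with diagnostics.
    """
    arch = arch or VaeArch()
    X = onehot_encode(msa).reshape(msa.n_seq, -1)
    model = VAE(msa.length, arch)
    rng = np.random.default_rng(arch.seed + 1)
    trace = np.empty(arch.epochs)
    for epoch in range(arch.epochs):
        eps = rng.standard_normal((msa.n_seq, arch.latent_dim))
        elbo = model._step(X, eps)
        if not np.isfinite(elbo):
            raise FloatingPointError(
                f"VAE training diverged at epoch {epoch} (ELBO={elbo}); "
                "lower the learning rate"
            )
        trace[epoch] = elbo
    return model, trace


def sequence_elbo(
    model: VAE, sequence: str, n_samples: int = 2000, seed: int = 0
) -> float:
    """Importance-weighted ELBO estimate of one sequence's log-likelihood.

    Draws n posterior samples z ~ q(z|x) and returns
    logmeanexp[log p(x|z) + log p(z) - log q(z|x)].
    """
    x = onehot_encode(MSA([sequence])).reshape(1, -1)
    mu, logvar, *_ = model.encode(x)
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((n_samples, model.arch.latent_dim))
    std = np.exp(0.5 * logvar)
    Z = mu + eps * std
    X = np.repeat(x, n_samples, axis=0)
    log_px = model.log_px_given_z(X, Z)
    log_pz = -0.5 * np.sum(Z**2 + np.log(2 * np.pi), axis=1)
    log_qz = -0.5 * np.sum(eps**2 + np.log(2 * np.pi) + logvar, axis=1)
    return float(logsumexp(log_px + log_pz - log_qz) - np.log(n_samples))


_MUTATION_RE = re.compile(r"^([A-Y])(\d+)([A-Y\-])$")


def parse_mutation(label: str) -> tuple[str, int, str]:
    """Parse 'V648E' into (wt residue, 1-based position, mutant residue)."""
    m = _MUTATION_RE.match(label.strip())
    if not m or m.group(1) not in ALPHABET or m.group(3) not in ALPHABET:
        raise ValueError(f"cannot parse mutation label {label!r}")
    return m.group(1), int(m.group(2)), m.group(3)


def mutation_fitness(
    model: VAE,
    wt_sequence: str,
    mutation: str,
    n_posterior_samples: int = 2000,
    seed: int = 0,
) -> float:
    """Evolutionary fitness score of a point mutation (lower = fitter).

    score = -[ELBO(mutant) - ELBO(WT)], both estimated with the same
    posterior-sample seed (common random numbers) to reduce variance.
    The wild type scored against itself gives exactly 0.
    """
    wt_aa, pos, mut_aa = parse_mutation(mutation)
    if pos < 1 or pos > len(wt_sequence):
        raise ValueError(f"position {pos} outside sequence of length {len(wt_sequence)}")
    observed = wt_sequence[pos - 1]
    if observed != wt_aa:
        raise ValueError(
            f"mutation {mutation}: wild-type sequence has {observed!r} at position {pos}"
        )
    mutant = wt_sequence[: pos - 1] + mut_aa + wt_sequence[pos:]
    elbo_wt = sequence_elbo(model, wt_sequence, n_posterior_samples, seed)
    if mutant == wt_sequence:
        return 0.0
    elbo_mut = sequence_elbo(model, mutant, n_posterior_samples, seed)
    return float(-(elbo_mut - elbo_wt))


# --- structure-based interface selection ----------------------------------

def interface_contacts(structure, cutoff: float = 5.5):
    """Inter-chain residue contacts of a dimer by heavy-atom distance.

    ``structure`` is a biotite AtomArray with at least two chains.
    Returns (contacts, interface_residues): contacts is a list of
    (res_id_A, res_id_B, min heavy-atom distance) for pairs closer than
    ``cutoff`` A, and interface_residues the set of residue ids involved
    (both chains pooled).  Neighbour search uses a KD-tree; equivalent to
    the all-pairs brute force.
    """
    chains = np.unique(structure.chain_id)
    if len(chains) < 2:
        raise ValueError("need at least two chains")
    heavy = structure[structure.element != "H"]
    contacts = []
    interface: set[int] = set()
    for a_idx in range(len(chains)):
        for b_idx in range(a_idx + 1, len(chains)):
            A = heavy[heavy.chain_id == chains[a_idx]]
            B = heavy[heavy.chain_id == chains[b_idx]]
            tree = cKDTree(B.coord)
            pairs: dict[tuple[int, int], float] = {}
            neighbor_lists = tree.query_ball_point(A.coord, cutoff)
            for i, nbrs in enumerate(neighbor_lists):
                for j in nbrs:
                    d = float(np.linalg.norm(A.coord[i] - B.coord[j]))
                    key = (int(A.res_id[i]), int(B.res_id[j]))
                    if d < pairs.get(key, np.inf):
                        pairs[key] = d
            for (ra, rb), d in sorted(pairs.items()):
                if d < cutoff:
                    contacts.append((ra, rb, d))
                    interface.add(ra)
                    interface.add(rb)
    return contacts, interface


def rank_interface_mutations(
    scores: pd.DataFrame, interface: set[int], top_k: int | None = None
) -> pd.DataFrame:
    """Rank candidate mutations at the interface by fitness score.

    ``scores`` has columns ``mutation`` and ``score`` (lower = fitter).
    Filters to interface positions, sorts ascending by score with a
    stable tie-break by position then mutant residue, and returns the
    top ``top_k`` rows.
    """
    if scores.empty:
        raise ValueError("scores table is empty")
    parsed = [parse_mutation(m) for m in scores["mutation"]]
    df = scores.copy()
    df["_pos"] = [p for _, p, _ in parsed]
    df["_mut"] = [m for _, _, m in parsed]
    df = df[df["_pos"].isin(interface)]
    df = df.sort_values(["score", "_pos", "_mut"], kind="stable")
    df = df.drop(columns=["_pos", "_mut"]).reset_index(drop=True)
    if top_k is not None:
        df = df.head(top_k)
    return df


def buried_surface_fraction(complex_structure, probe: float = 1.4, point_number: int = 1000) -> float:
    """Percentage of solvent-accessible surface buried on complexation.

    100 * (sum SASA(chains alone) - SASA(complex)) / sum SASA(chains
    alone), with SASA by Shrake-Rupley point sampling (>= 960 points per
    atom) using single-element van der Waals radii.
    """
    chains = np.unique(complex_structure.chain_id)
    if len(chains) < 2:
        raise ValueError("need at least two chains")
    point_number = max(point_number, 960)

    def total_sasa(arr) -> float:
        vals = struc.sasa(
            arr, probe_radius=probe, point_number=point_number, vdw_radii="Single"
        )
        return float(np.nansum(vals))

    sasa_complex = total_sasa(complex_structure)
    sasa_alone = sum(
        total_sasa(complex_structure[complex_structure.chain_id == c]) for c in chains
    )
    return 100.0 * (sasa_alone - sasa_complex) / sasa_alone
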