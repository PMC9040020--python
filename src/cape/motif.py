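"""Convert first-layer convolution kernels into PWMs and export MEME files.

A position i of a sequence activates a kernel when the pre-ReLU, bias-free
convolution sum exceeds a fraction alpha of the kernel's extreme activation
value (EAV) — the largest response any one-hot input can produce.  The
subsequences at activated positions are pooled into per-column base counts
and normalized into a position weight matrix.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from io import StringIO
from typing import Sequence

import numpy as np

from cape.core_io import ALPHABET, SequenceRecord, one_hot_encode
from cape.network import ConvKernel

DEFAULT_ALPHA = 0.9
DEFAULT_PSEUDOCOUNT = 0.1


@dataclass(frozen=True)
class ActivationRule:
    alpha: float = DEFAULT_ALPHA
    kernel_length: int = 8

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class PWM:
    """Row-stochastic motif matrix (kernel_length × 4, columns A,C,G,T)."""

    probs: np.ndarray
    n_sites: int
    name: str = "motif"
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be an L×4 matrix")
        if (self.probs < 0).any():
            raise ValueError("negative PWM entry")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))


def extreme_activation_value(kernel: ConvKernel) -> float:
    """Largest bias-free response over one-hot inputs: sum of row maxima."""
    return float(kernel.weights.max(axis=1).sum())


def _scan_scores(kernel: ConvKernel, onehot: np.ndarray) -> np.ndarray:
    """Pre-ReLU, bias-free convolution scores at every valid position."""
    m = kernel.weights.shape[0]
    length = onehot.shape[0]
    if length < m:
        raise ValueError(f"sequence length {length} shorter than kernel {m}")
    win = np.lib.stride_tricks.sliding_window_view(onehot, m, axis=0)  # (L-m+1, 4, m)
    return np.einsum("pnm,mn->p", win, kernel.weights)


def activated_positions(
    kernel: ConvKernel, seq: np.ndarray | SequenceRecord | str,
    rule: ActivationRule = ActivationRule(),
) -> list[int]:
    """Positions whose subsequence activates the kernel (strict threshold)."""
    onehot = seq if isinstance(seq, np.ndarray) else one_hot_encode(seq)
    threshold = rule.alpha * extreme_activation_value(kernel)
    scores = _scan_scores(kernel, onehot)
    return [int(i) for i in np.flatnonzero(scores > threshold)]


def kernel_to_pwm(
    kernel: ConvKernel,
    sequences: Sequence[SequenceRecord | str],
    rule: ActivationRule = ActivationRule(),
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    name: str = "motif",
) -> PWM | None:
    """Pool the subsequences at activated positions into a PWM.

    Subsequences containing N are skipped.  Returns ``None`` when no
    position of any sequence activates the kernel.
    """
    m = kernel.weights.shape[0]
    counts = np.zeros((m, 4), dtype=np.float64)
    n_sites = 0
    for rec in sequences:
        seq = rec.seq if isinstance(rec, SequenceRecord) else rec
        if len(seq) < m:
            continue
        onehot = one_hot_encode(seq)
        for pos in activated_positions(kernel, onehot, rule):
            sub = seq[pos:pos + m]
            if "N" in sub:
                continue
            counts += onehot[pos:pos + m]
            n_sites += 1
    if n_sites == 0:
        return None
    counts += pseudocount
    probs = counts / counts.sum(axis=1, keepdims=True)
    return PWM(probs=probs, n_sites=n_sites, name=name, pseudocount=pseudocount)


def extract_motifs(
    kernels: Sequence[ConvKernel],
    sequences: Sequence[SequenceRecord | str],
    rule: ActivationRule = ActivationRule(),
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[list[PWM], list[int]]:
    """PWMs for every kernel with a positive EAV and at least one activation.

    Returns the PWMs and the indices of skipped kernels.
    """
    pwms, skipped = [], []
    for i, kernel in enumerate(kernels):
        if extreme_activation_value(kernel) <= 0:
            skipped.append(i)
            continue
        pwm = kernel_to_pwm(kernel, sequences, rule, pseudocount,
                            name=f"kernel_{i}")
        if pwm is None:
            skipped.append(i)
        else:
            pwms.append(pwm)
    return pwms, skipped


def discover_motifs(
    x_dna: np.ndarray,
    labels: np.ndarray,
    sequences: Sequence[SequenceRecord | str],
    n_restarts: int = 6,
    epochs: int = 150,
    seed: int = 0,
    n_kernels: int = 16,
    rule: ActivationRule = ActivationRule(),
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[PWM]:
    """Multi-start motif discovery: train motif-scanner networks and pool
    the PWMs extracted from their first-layer kernels.

    Kernel convergence to a clean motif is a matter of initialization luck
    (as in any multi-start motif finder), so several restarts with
    different seeds are trained and all extracted PWMs returned.
    ``x_dna`` is (n, L, 4) one-hot windows with 0/1 ``labels``;
    ``sequences`` are the (positive) sequences scanned for activations.
    """
    from cape import network, nn

    pwms: list[PWM] = []
    for r in range(n_restarts):
        cfg = network.NetworkConfig.motif_scanner(
            n_kernels=n_kernels, latent_len=x_dna.shape[1]
        )
        model = network.EnhancerNetwork(cfg, seed=(seed + 7919 * r + 1) % 2 ** 31)
        rng = np.random.default_rng((seed + 104729 * r + 2) % 2 ** 31)
        opt = nn.Adam(model.params(), lr=cfg.learning_rate)
        for _ in range(epochs):
            network._run_epoch(model, x_dna, None, labels, opt,
                               cfg.batch_size, rng)
        extracted, _ = extract_motifs(
            model.first_layer_kernels("dna"), sequences, rule, pseudocount
        )
        for p in extracted:
            p.name = f"restart{r}_{p.name}"
        pwms.extend(extracted)
    return pwms


def pwm_column_correlation(a: PWM | np.ndarray, b: PWM | np.ndarray) -> float:
    """Mean per-column Pearson correlation between two same-length PWMs.

    Columns here are motif positions (rows of the L×4 matrix); each
    position's 4 base probabilities are correlated and the mean over
    positions is returned.  Constant 4-vectors correlate as 0.
    """
    pa = a.probs if isinstance(a, PWM) else np.asarray(a, dtype=np.float64)
    pb = b.probs if isinstance(b, PWM) else np.asarray(b, dtype=np.float64)
    if pa.shape != pb.shape:
        raise ValueError(f"shape mismatch {pa.shape} vs {pb.shape}")
    cors = []
    for ra, rb in zip(pa, pb):
        sa, sb = ra - ra.mean(), rb - rb.mean()
        denom = np.sqrt((sa ** 2).sum() * (sb ** 2).sum())
        cors.append(0.0 if denom == 0 else float((sa * sb).sum() / denom))
    return float(np.mean(cors))


def write_meme(
    pwms: Sequence[PWM],
    path: str | os.PathLike | None = None,
    background: Sequence[float] | None = None,
) -> str:
    """Write PWMs in MEME minimal format; returns the text."""
    if len(pwms) == 0:
        raise ValueError("no PWMs to write")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    out = StringIO()
    out.write("MEME version 4\n\n")
    out.write("ALPHABET= ACGT\n\n")
    out.write("strands: + -\n\n")
    out.write("Background letter frequencies\n")
    out.write(" ".join(f"{b} {bg[i]:.4f}" for i, b in enumerate(ALPHABET)) + "\n\n")
    for pwm in pwms:
        out.write(f"MOTIF {pwm.name}\n")
        out.write(
            f"letter-probability matrix: alength= 4 w= {pwm.length} "
            f"nsites= {pwm.n_sites} E= 0\n"
        )
        for row in pwm.probs:
            out.write(" ".join(f"{v:.8f}" for v in row) + "\n")
        out.write("\n")
    text = out.getvalue()
    if path is not None:
        with open(path, "w") as handle:
            handle.write(text)
    return text


def read_meme(source: str | os.PathLike) -> list[PWM]:
    """Parse a MEME minimal-format file (or text) back into PWMs."""
    if isinstance(source, str) and "\n" in source:
        lines = source.splitlines()
    else:
        with open(source) as handle:
            lines = handle.read().splitlines()
    pwms = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            name = line.split()[1] if len(line.split()) > 1 else "motif"
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability"
            ):
                i += 1
            header = lines[i].strip()
            tokens = header.replace("letter-probability matrix:", "").split()
            meta = {tokens[j].rstrip("="): tokens[j + 1]
                    for j in range(0, len(tokens) - 1, 2)}
            width = int(meta.get("w", 0))
            n_sites = int(meta.get("nsites", 1))
            rows = []
            i += 1
            while len(rows) < width:
                vals = [float(v) for v in lines[i].split()]
                rows.append(vals)
                i += 1
            probs = np.asarray(rows)
            probs = probs / probs.sum(axis=1, keepdims=True)
            pwms.append(PWM(probs=probs, n_sites=n_sites, name=name))
        else:
            i += 1
    return pwms


def validate_meme(text: str) -> bool:
    """Check MEME minimal-format structure: version line, alphabet,
    and row-stochastic letter-probability matrices of the declared width."""
    if "MEME version" not in text.splitlines()[0]:
        return False
    if not any(l.startswith("ALPHABET=") for l in text.splitlines()):
        return False
    try:
        pwms = read_meme(text)
    except Exception:
        return False
    return len(pwms) > 0
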