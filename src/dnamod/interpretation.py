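"""Model interpretation: integrated gradients, attribution-driven motif
discovery, the nucleotide-masking experiment, and cross-modification
correlation.

Integrated gradients attribute a prediction to input features by
averaging the gradient of the target-class logit along a straight path
from a zero-embedding baseline to the actual embedded input (50
interpolation points by default) and multiplying elementwise by the
input-minus-baseline difference.  Per-token scalars are the sum over
embedding dimensions, so the completeness axiom — attributions sum to
F(x) − F(baseline) — holds at token level up to the discretization
residual, which is recorded.

The motif pipeline keeps samples whose true-class probability exceeds
0.3, extracts the site ±5 segment (11 bases, 10 flanking units) with
its attributions, embeds one-hot-encoded segments with UMAP, clusters
with DBSCAN, and summarizes each cluster by its mean attribution
profile and a pseudocount position weight matrix exportable in MEME
minimal format for downstream comparison tools such as TOMTOM.

The masking experiment replaces randomly chosen token positions with
the [CLS] id — inside the motif span (never the modification site
itself) or outside it (never the leading [CLS] token) — and measures
the drop in class recall over repeated draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .records import (
    LABELS,
    LABEL_TO_ID,
    SITE_INDEX,
    SITE_TOKEN_INDEX,
    TOKEN_LENGTH,
    VOCABULARY,
    CLS_TOKEN,
    SequenceRecord,
    encode_dataset,
    tokenize,
)
from .network import MethylationClassifier

SELECTION_THRESHOLD = 0.3
IG_STEPS = 50
SEGMENT_FLANK = 5
MIN_MASKING_REPS = 10

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


# ---------------------------------------------------------------------------
# integrated gradients
# ---------------------------------------------------------------------------

@dataclass
class AttributionTrack:
    """Per-token integrated-gradient scalars for one sequence."""

    token_attributions: np.ndarray  # length 42
    target_class: str
    predicted_probability: float
    completeness_residual: float
    record_id: str | None = None


def select_samples(
    model: MethylationClassifier,
    records: Sequence[SequenceRecord],
    threshold: float = SELECTION_THRESHOLD,
) -> list[SequenceRecord]:
    """Keep records whose true-class probability is strictly above ``threshold``."""
    if not records:
        return []
    tokens, labels = encode_dataset(records)
    probs = model.predict_proba(tokens)
    true_probs = probs[np.arange(len(records)), labels]
    return [rec for rec, p in zip(records, true_probs) if p > threshold]


def integrated_gradients(
    model,
    tokens,
    target_class: int | str,
    steps: int = IG_STEPS,
    record_id: str | None = None,
) -> AttributionTrack:
    """Integrated gradients of the target-class logit w.r.t. the embedding.

    ``model`` must expose ``embed_tokens`` and ``logit_grads``; ``tokens``
    is a TokenSequence or a length-42 id array.  The path runs from the
    all-zero embedding to the embedded input, sampled at the
    right-endpoint coefficients k/steps, k = 1..steps.
    """
    if steps < 1:
        raise ValueError("steps must be at least 1")
    if isinstance(target_class, str):
        class_id = LABEL_TO_ID[target_class]
        class_name = target_class
    else:
        class_id = int(target_class)
        class_name = LABELS[class_id] if class_id < len(LABELS) else str(class_id)
    ids = np.asarray(getattr(tokens, "token_ids", tokens))

    emb = model.embed_tokens(ids)  # (42, dim)
    coeffs = np.arange(1, steps + 1, dtype=np.float64) / steps
    path = coeffs[:, None, None] * emb[None, :, :]
    _, grads = model.logit_grads(path, class_id)
    avg_grad = grads.mean(axis=0)
    attributions = (emb * avg_grad).sum(axis=-1)

    endpoint_logits, _ = model.logit_grads(
        np.stack([emb, np.zeros_like(emb)]), class_id
    )
    f_input, f_baseline = endpoint_logits
    residual = float(attributions.sum() - (f_input - f_baseline))

    probs = model.predict_proba(ids[None, :])[0] if hasattr(model, "predict_proba") \
        else None
    predicted = float(probs[class_id]) if probs is not None else float("nan")
    return AttributionTrack(
        token_attributions=attributions,
        target_class=class_name,
        predicted_probability=predicted,
        completeness_residual=residual,
        record_id=record_id,
    )


# ---------------------------------------------------------------------------
# segment extraction and clustering
# ---------------------------------------------------------------------------

@dataclass
class AttributionSegment:
    """Site-centered subsequence with aligned attributions."""

    bases: str
    attributions: np.ndarray
    record_id: str | None = None
    site_position: int = SITE_INDEX


def extract_segment(
    track: AttributionTrack,
    record: SequenceRecord,
    flank: int = SEGMENT_FLANK,
) -> AttributionSegment:
    """Site ± ``flank`` bases (length 2·flank+1) with aligned attributions."""
    if flank < 0:
        raise ValueError("flank must be nonnegative")
    lo, hi = SITE_INDEX - flank, SITE_INDEX + flank
    if lo < 0 or hi >= len(record.sequence):
        raise ValueError(
            f"flank {flank} pushes the segment outside the "
            f"{len(record.sequence)}-nt window"
        )
    bases = record.sequence[lo:hi + 1]
    token_lo = SITE_TOKEN_INDEX - flank
    attributions = np.asarray(track.token_attributions)[token_lo:token_lo + len(bases)]
    return AttributionSegment(
        bases=bases,
        attributions=attributions.copy(),
        record_id=record.id,
    )


@dataclass
class ClusterParams:
    """Manifold-embedding and density-clustering settings."""

    n_neighbors: int = 15
    n_components: int = 2
    min_cluster_size: int = 10
    eps: float | None = None  # None → 4-distance elbow heuristic
    seed: int = 0


@dataclass
class MotifCluster:
    """A cluster of attribution segments with its PWM summary."""

    cluster_id: int
    segments: list[AttributionSegment]
    mean_attribution: np.ndarray
    pwm: np.ndarray

    @property
    def size(self) -> int:
        return len(self.segments)

    def consensus(self) -> str:
        return "".join(_BASES[j] for j in self.pwm.argmax(axis=1))


def one_hot_segments(segments: Sequence[AttributionSegment]) -> np.ndarray:
    """(n, L·4) one-hot encoding of segment bases."""
    length = len(segments[0].bases)
    out = np.zeros((len(segments), length * 4))
    for i, seg in enumerate(segments):
        for j, base in enumerate(seg.bases):
            out[i, j * 4 + _BASE_INDEX[base]] = 1.0
    return out


def _elbow_eps(embedded: np.ndarray, k: int) -> float:
    """Epsilon from the sorted k-distance curve (max distance to its chord)."""
    from sklearn.neighbors import NearestNeighbors

    k = min(k, len(embedded) - 1)
    if k < 1:
        return 0.5
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedded)
    dists, _ = nn.kneighbors(embedded)
    curve = np.sort(dists[:, -1])
    if curve[-1] <= 0:
        return 0.5
    x = np.linspace(0.0, 1.0, len(curve))
    y = curve / curve[-1]
    elbow = int(np.argmax(x - y)) if len(curve) > 2 else len(curve) - 1
    eps = float(curve[elbow])
    return eps if eps > 0 else float(curve[-1])


def cluster_segments(
    segments: Sequence[AttributionSegment],
    params: ClusterParams | None = None,
) -> list[MotifCluster]:
    """Group one-hot-encoded segments by UMAP embedding + DBSCAN.

    Noise-labeled segments are dropped; clusters are returned largest
    first, each with the mean of its members' attribution vectors and a
    pseudocount PWM.  Deterministic for a fixed seed.
    """
    params = params or ClusterParams()
    segments = list(segments)
    if len(segments) < params.min_cluster_size:
        warnings.warn(
            f"only {len(segments)} segments, fewer than the minimum cluster "
            f"size {params.min_cluster_size}; returning no clusters",
            stacklevel=2,
        )
        return []
    encoded = one_hot_segments(segments)
    unique_rows = np.unique(encoded, axis=0)
    if len(unique_rows) == 1:
        # degenerate: all segments identical; manifold embedding is undefined
        return [_make_cluster(0, segments)]

    import umap
    from sklearn.cluster import DBSCAN

    n_neighbors = min(params.n_neighbors, len(segments) - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns on small n / fixed seed
        embedded = umap.UMAP(
            n_neighbors=n_neighbors,
            n_components=params.n_components,
            random_state=params.seed,
        ).fit_transform(encoded)
    eps = params.eps if params.eps is not None else _elbow_eps(
        embedded, params.min_cluster_size
    )
    labels = DBSCAN(eps=eps, min_samples=params.min_cluster_size).fit_predict(embedded)

    clusters = []
    for label in sorted(set(labels) - {-1}):
        members = [seg for seg, l in zip(segments, labels) if l == label]
        clusters.append(members)
    clusters.sort(key=len, reverse=True)
    return [_make_cluster(i, members) for i, members in enumerate(clusters)]


def _make_cluster(cluster_id: int, members: list[AttributionSegment]) -> MotifCluster:
    return MotifCluster(
        cluster_id=cluster_id,
        segments=members,
        mean_attribution=np.mean([m.attributions for m in members], axis=0),
        pwm=build_pwm(members),
    )


def build_pwm(
    segments: Sequence[AttributionSegment] | MotifCluster,
    pseudocount: float = 0.01,
) -> np.ndarray:
    """Column-stochastic (L, 4) base-frequency matrix with pseudocounts."""
    if isinstance(segments, MotifCluster):
        segments = segments.segments
    segments = list(segments)
    if not segments:
        raise ValueError("cannot build a PWM from an empty cluster")
    length = len(segments[0].bases)
    counts = np.full((length, 4), pseudocount, dtype=float)
    for seg in segments:
        for j, base in enumerate(seg.bases):
            counts[j, _BASE_INDEX[base]] += 1.0
    return counts / counts.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# MEME minimal format
# ---------------------------------------------------------------------------

def export_meme(
    clusters: Sequence[MotifCluster],
    path: str | Path,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> None:
    """Write cluster PWMs as a MEME minimal-format motif file."""
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: +",
        "",
        "Background letter frequencies",
        " ".join(f"{b} {f:.6f}" for b, f in zip(_BASES, background)),
        "",
    ]
    for cluster in clusters:
        width = cluster.pwm.shape[0]
        lines.append(f"MOTIF cluster_{cluster.cluster_id} {cluster.consensus()}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {width} "
            f"nsites= {cluster.size} E= 0"
        )
        for row in cluster.pwm:
            lines.append(" " + " ".join(f"{v:.6f}" for v in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_meme(path: str | Path) -> dict[str, np.ndarray]:
    """Parse a MEME minimal file back to {motif name: (w, 4) matrix}."""
    motifs: dict[str, np.ndarray] = {}
    name = None
    rows: list[list[float]] = []
    expected = 0
    for line in Path(path).read_text().splitlines():
        stripped = line.strip()
        if stripped.startswith("MOTIF"):
            if name is not None and rows:
                motifs[name] = np.array(rows)
            name = stripped.split()[1]
            rows = []
            expected = 0
        elif stripped.startswith("letter-probability matrix"):
            parts = stripped.split()
            expected = int(parts[parts.index("w=") + 1])
        elif name is not None and len(rows) < expected and stripped \
                and stripped[0] in "0123456789.":
            rows.append([float(v) for v in stripped.split()])
    if name is not None and rows:
        motifs[name] = np.array(rows)
    return motifs


# ---------------------------------------------------------------------------
# end-to-end motif discovery
# ---------------------------------------------------------------------------

def discover_motifs(
    model: MethylationClassifier,
    records: Sequence[SequenceRecord],
    threshold: float = SELECTION_THRESHOLD,
    steps: int = IG_STEPS,
    flank: int = SEGMENT_FLANK,
    cluster_params: ClusterParams | None = None,
) -> dict[str, list[MotifCluster]]:
    """Per-class pipeline: select → attribute → segment → cluster."""
    out: dict[str, list[MotifCluster]] = {}
    for label in LABELS:
        class_records = [r for r in records if r.label == label]
        if not class_records:
            continue
        selected = select_samples(model, class_records, threshold)
        segments = []
        for rec in selected:
            track = integrated_gradients(
                model, tokenize(rec), rec.label, steps=steps, record_id=rec.id
            )
            segments.append(extract_segment(track, rec, flank))
        if segments:
            out[label] = cluster_segments(segments, cluster_params)
        else:
            out[label] = []
    return out


# ---------------------------------------------------------------------------
# nucleotide masking experiment
# ---------------------------------------------------------------------------

@dataclass
class MaskingExperimentResult:
    """Recall under repeated random masking inside vs. outside a motif span."""

    modification_class: str
    motif: str
    mean_recall_inside: float
    std_inside: float
    mean_recall_outside: float
    std_outside: float
    n_repetitions: int
    n_masked_positions: int


def _eligible_positions(span: tuple[int, int], mode: str) -> np.ndarray:
    """Maskable token positions for one record.

    ``span`` is a 0-based half-open interval in window (sequence)
    coordinates; token position = sequence position + 1.  Inside mode
    excludes the modification site; outside mode excludes the leading
    [CLS] token.
    """
    start, end = span
    if not (0 <= start < end <= TOKEN_LENGTH - 1):
        raise ValueError(f"motif span {span} outside the 41-nt window")
    inside_tokens = set(range(start + 1, end + 1)) - {SITE_TOKEN_INDEX}
    if mode == "inside":
        eligible = inside_tokens
    elif mode == "outside":
        eligible = set(range(1, TOKEN_LENGTH)) - set(range(start + 1, end + 1))
    else:
        raise ValueError("mode must be 'inside' or 'outside'")
    return np.array(sorted(eligible))


def masked_recall(
    model: MethylationClassifier,
    records: Sequence[SequenceRecord],
    spans: dict[str, tuple[int, int]] | tuple[int, int],
    mode: str,
    n_positions: int,
    n_reps: int = MIN_MASKING_REPS,
    seed: int = 0,
) -> tuple[float, float]:
    """(mean, std) class recall over ``n_reps`` random masking draws."""
    if n_reps < MIN_MASKING_REPS:
        raise ValueError(f"at least {MIN_MASKING_REPS} repetitions are required")
    records = list(records)
    classes = {r.label for r in records}
    if len(classes) != 1:
        raise ValueError("masking evaluates one modification class at a time")
    class_id = LABEL_TO_ID[classes.pop()]
    tokens, _ = encode_dataset(records)
    cls_id = VOCABULARY[CLS_TOKEN]

    per_record_eligible = []
    for rec in records:
        span = spans[rec.id] if isinstance(spans, dict) else spans
        eligible = _eligible_positions(tuple(span), mode)
        if n_positions > len(eligible):
            raise ValueError(
                f"n_positions={n_positions} exceeds the {len(eligible)} "
                f"eligible {mode} positions for record {rec.id!r}"
            )
        per_record_eligible.append(eligible)

    rng = np.random.default_rng(seed)
    recalls = []
    for _ in range(n_reps):
        masked = tokens.copy()
        if n_positions > 0:
            for i, eligible in enumerate(per_record_eligible):
                chosen = rng.choice(eligible, size=n_positions, replace=False)
                masked[i, chosen] = cls_id
        predicted = model.predict(masked)
        recalls.append(float((predicted == class_id).mean()))
    return float(np.mean(recalls)), float(np.std(recalls))


def masking_experiment(
    model: MethylationClassifier,
    records: Sequence[SequenceRecord],
    spans: dict[str, tuple[int, int]] | tuple[int, int],
    n_positions: int,
    n_reps: int = MIN_MASKING_REPS,
    seed: int = 0,
    motif: str = "",
) -> MaskingExperimentResult:
    """Run both masking modes and collect the paired result."""
    label = records[0].label
    mean_in, std_in = masked_recall(
        model, records, spans, "inside", n_positions, n_reps, seed
    )
    mean_out, std_out = masked_recall(
        model, records, spans, "outside", n_positions, n_reps, seed
    )
    return MaskingExperimentResult(
        modification_class=label,
        motif=motif,
        mean_recall_inside=mean_in,
        std_inside=std_in,
        mean_recall_outside=mean_out,
        std_outside=std_out,
        n_repetitions=n_reps,
        n_masked_positions=n_positions,
    )


# ---------------------------------------------------------------------------
# cross-modification correlation
# ---------------------------------------------------------------------------

def class_correlation(
    model: MethylationClassifier,
    records: Sequence[SequenceRecord],
    method: str = "pearson",
    batch_size: int = 256,
) -> np.ndarray:
    """5×5 correlation between per-class mean last-hidden representations.

    For every class the flattened [CLS]-row of the last hidden layer is
    averaged over that class's records; the matrix is the pairwise
    Pearson (or Spearman) correlation of those mean vectors, in the
    fixed class order 4mC, 5hmC, 5mC, 6mA, 6mA-neg.
    """
    present = {r.label for r in records}
    missing = set(LABELS) - present
    if missing:
        raise ValueError(f"classes missing from the dataset: {sorted(missing)}")
    tokens, labels = encode_dataset(records)
    reps = []
    for start in range(0, len(tokens), batch_size):
        stages = model.forward(tokens[start:start + batch_size])
        reps.append(stages["last_hidden"].data[:, 0, :])  # [CLS] row
    reps = np.concatenate(reps, axis=0)
    means = np.stack([reps[labels == LABEL_TO_ID[l]].mean(axis=0) for l in LABELS])
    if method == "pearson":
        return np.corrcoef(means)
    if method == "spearman":
        from scipy.stats import spearmanr

        rho, _ = spearmanr(means.T)
        return np.asarray(rho)
    raise ValueError("method must be 'pearson' or 'spearman'")
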