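"""Penalty-score elicitation from a pluggable text-generation provider.

A provider turns prompt text into response text.  Three implementations
satisfy the contract: a live HTTP endpoint (OpenAI-style chat completions,
greedy decoding at temperature 0), a file-backed score table that bypasses
prompting entirely, and a deterministic mock that scores each feature from
a seeded hash of its name so the whole pipeline runs offline.

Because providers can hallucinate, parsing is strict: every requested
feature must be scored, scores must be positive finite numbers, and
out-of-range values are clipped to [SCORE_FLOOR, SCORE_CAP] with a warning.
Responses are cached on disk keyed by (provider identity, prompt hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import re
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

SCORE_FLOOR = 1e-3
SCORE_CAP = 1e3


class ResponseParseError(ValueError):
    """Provider response could not be validated into scores."""


@dataclass
class PenaltyScores:
    """Strictly positive per-feature penalty factors s_j (small = important)."""

    values: np.ndarray
    provenance: str = "mock"  # llm | file | mock
    raw_response_hash: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("scores must be a 1-D vector")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("penalty scores must be strictly positive and finite")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class PromptSpec:
    """Components of the penalty-elicitation prompt.

    task_description carries the dataset background, the scoring task and
    the output-format instructions; category names the contrast being
    studied; system_context is the system-role preamble.
    """

    feature_names: tuple[str, ...]
    category: str = "schizophrenia vs normal control"
    task_description: str = (
        "The features are functional connectivity (FC) strengths between "
        "pairs of brain regions (AAL atlas naming), estimated from "
        "resting-state fMRI. Assign each listed edge a PENALTY factor "
        "reflecting its relevance to the category: edges with strong "
        "neuroscientific evidence of abnormality receive SMALL penalties "
        "(near 0.1), irrelevant edges receive LARGE penalties (near 2.0)."
    )
    system_context: str = (
        "You are a neuroscience domain expert scoring brain-connectivity "
        "features for penalized feature selection."
    )

    def __post_init__(self) -> None:
        self.feature_names = tuple(self.feature_names)
        if not self.feature_names:
            raise ValueError("feature_names must be non-empty")


@dataclass
class ProviderConfig:
    """How to reach (or emulate) the scoring provider."""

    provider: str = "mock"  # mock | file | http
    endpoint: str = ""
    model: str = ""
    api_key_env: str = "FCEXPLAIN_API_KEY"
    temperature: float = 0.0
    chunk_size: int = 200
    cache_dir: str | None = None
    seed: int = 0
    scores_path: str | None = None  # for provider == "file"
    max_retries: int = 2


def build_penalty_prompt(spec: PromptSpec, chunk: tuple[str, ...] | list[str]) -> str:
    """Render the scoring prompt for one chunk of feature names.

    Deterministic in (spec, chunk); lists each name exactly once and ends
    with the machine-readable output-format instruction.
    """
    chunk = tuple(chunk)
    if not chunk:
        raise ValueError("chunk must be non-empty")
    lines = [
        spec.task_description,
        "",
        f"Category: {spec.category}",
        "",
        "Features to score:",
    ]
    lines += [f"- {name}" for name in chunk]
    lines += [
        "",
        "Output format: one line per feature, exactly",
        "<feature name>: <positive number>",
        "No other text.",
    ]
    return "\n".join(lines)


_SCORE_LINE = re.compile(r"^\s*(?P<name>.+?)\s*[:=,\t]\s*(?P<score>[-+0-9.eE]+)\s*$")


def parse_penalty_response(
    text: str, expected_names: tuple[str, ...] | list[str]
) -> np.ndarray:
    """Validate a provider response into one positive score per expected name.

    Unknown names are ignored with a warning; non-positive or out-of-range
    scores are clipped to [SCORE_FLOOR, SCORE_CAP] with a warning; a missing
    name or an unparseable value is a hard error naming the offender.
    """
    expected = list(expected_names)
    found: dict[str, float] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        m = _SCORE_LINE.match(line)
        if m is None:
            continue
        name = m.group("name").strip().strip("-* ").strip()
        try:
            score = float(m.group("score"))
        except ValueError:
            raise ResponseParseError(
                f"unparseable score for {name!r}: {m.group('score')!r}"
            ) from None
        if name not in expected:
            logger.warning("ignoring unknown feature name %r in response", name)
            continue
        if not np.isfinite(score) or score < SCORE_FLOOR or score > SCORE_CAP:
            clipped = float(np.clip(score if np.isfinite(score) else SCORE_FLOOR,
                                    SCORE_FLOOR, SCORE_CAP))
            logger.warning("score %r for %s clipped to %g", score, name, clipped)
            score = clipped
        found[name] = score
    missing = [n for n in expected if n not in found]
    if missing:
        raise ResponseParseError(
            f"response missing score for {missing[0]!r} "
            f"({len(missing)} of {len(expected)} names absent)"
        )
    return np.array([found[n] for n in expected], dtype=float)


# ---------------------------------------------------------------------------
# Providers


class MockProvider:
    """Deterministic offline provider: seeded hash of each feature name."""

    name = "mock"

    def __init__(self, config: ProviderConfig):
        self.seed = config.seed

    def _score(self, feature_name: str) -> float:
        digest = hashlib.sha256(
            f"{self.seed}:{feature_name}".encode()
        ).digest()
        u = int.from_bytes(digest[:8], "big") / 2**64  # uniform in [0, 1)
        return round(0.1 + 1.9 * u, 4)  # within [0.1, 2.0)

    def complete(self, prompt: str, system: str = "") -> str:
        names = [
            line[2:] for line in prompt.splitlines() if line.startswith("- ")
        ]
        return "\n".join(f"{n}: {self._score(n)}" for n in names)

    @property
    def identity(self) -> str:
        return f"mock:{self.seed}"


class HTTPProvider:
    """OpenAI-style chat-completions endpoint, greedy decoding (T = 0)."""

    name = "http"

    def __init__(self, config: ProviderConfig):
        if not config.endpoint:
            raise ValueError("http provider requires an endpoint URL")
        self.config = config

    def complete(self, prompt: str, system: str = "") -> str:
        import urllib.request

        payload = {
            "model": self.config.model,
            "temperature": self.config.temperature,
            "messages": (
                [{"role": "system", "content": system}] if system else []
            ) + [{"role": "user", "content": prompt}],
        }
        req = urllib.request.Request(
            self.config.endpoint,
            data=json.dumps(payload).encode(),
            headers={
                "Content-Type": "application/json",
                "Authorization": f"Bearer {os.environ.get(self.config.api_key_env, '')}",
            },
        )
        with urllib.request.urlopen(req, timeout=120) as resp:
            body = json.load(resp)
        return body["choices"][0]["message"]["content"]

    @property
    def identity(self) -> str:
        return f"http:{self.config.endpoint}:{self.config.model}"


def make_provider(config: ProviderConfig):
    if config.provider == "mock":
        return MockProvider(config)
    if config.provider == "http":
        return HTTPProvider(config)
    raise ValueError(f"unknown provider {config.provider!r}")


# ---------------------------------------------------------------------------
# Caching + assembly


class ResponseCache:
    """Disk cache of provider responses keyed by (identity, prompt) hash."""

    def __init__(self, cache_dir: str | None):
        self.cache_dir = cache_dir
        if cache_dir:
            os.makedirs(cache_dir, exist_ok=True)

    def _key(self, identity: str, prompt: str) -> str:
        return hashlib.sha256(f"{identity}\x00{prompt}".encode()).hexdigest()

    def get(self, identity: str, prompt: str) -> str | None:
        if not self.cache_dir:
            return None
        path = os.path.join(self.cache_dir, self._key(identity, prompt) + ".txt")
        if os.path.exists(path):
            with open(path) as fh:
                return fh.read()
        return None

    def put(self, identity: str, prompt: str, response: str) -> None:
        if not self.cache_dir:
            return
        path = os.path.join(self.cache_dir, self._key(identity, prompt) + ".txt")
        with open(path, "w") as fh:
            fh.write(response)


def importance_to_penalty(importance: np.ndarray, offset: float = 1e-2) -> np.ndarray:
    """Invert importance scores (large = important) into penalty factors."""
    importance = np.asarray(importance, dtype=float)
    return 1.0 / (np.abs(importance) + offset)


def load_scores_file(path: str, expected_names: tuple[str, ...]) -> PenaltyScores:
    """Read a two-column (edge name, score) delimited file with header."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"scores file {path} needs two columns (name, score)")
    name_col, score_col = df.columns[:2]
    lookup = dict(zip(df[name_col].astype(str), df[score_col].astype(float)))
    missing = [n for n in expected_names if n not in lookup]
    if missing:
        raise ValueError(f"scores file missing edge {missing[0]!r}")
    values = np.clip([lookup[n] for n in expected_names], SCORE_FLOOR, SCORE_CAP)
    h = hashlib.sha256(open(path, "rb").read()).hexdigest()
    return PenaltyScores(values=values, provenance="file", raw_response_hash=h)


def score_features(
    feature_names: tuple[str, ...] | list[str],
    spec: PromptSpec | None = None,
    config: ProviderConfig | None = None,
) -> PenaltyScores:
    """Assemble a full-length penalty-score vector by chunked prompting.

    Features are scored in fixed-size chunks sharing the system context;
    each chunk's response is parsed strictly and cached.  With
    ``provider="file"`` the provider is bypassed and the scores table read
    directly.
    """
    feature_names = tuple(feature_names)
    config = config or ProviderConfig()
    if config.provider == "file":
        if not config.scores_path:
            raise ValueError("file provider requires scores_path")
        return load_scores_file(config.scores_path, feature_names)
    spec = spec or PromptSpec(feature_names=feature_names)
    provider = make_provider(config)
    cache = ResponseCache(config.cache_dir)
    chunks = [
        feature_names[i : i + config.chunk_size]
        for i in range(0, len(feature_names), config.chunk_size)
    ]
    parts: list[np.ndarray] = []
    hasher = hashlib.sha256()
    for chunk in chunks:
        prompt = build_penalty_prompt(spec, chunk)
        response = cache.get(provider.identity, prompt)
        if response is None:
            last_err: Exception | None = None
            for _ in range(config.max_retries + 1):
                try:
                    response = provider.complete(prompt, system=spec.system_context)
                    parse_penalty_response(response, chunk)  # validate before caching
                    break
                except (ResponseParseError, OSError) as e:
                    last_err = e
                    response = None
            if response is None:
                raise RuntimeError(
                    f"provider failed on chunk starting {chunk[0]!r}: {last_err}"
                )
            cache.put(provider.identity, prompt, response)
        parts.append(parse_penalty_response(response, chunk))
        hasher.update(response.encode())
    values = np.concatenate(parts)
    provenance = "mock" if config.provider == "mock" else "llm"
    return PenaltyScores(values=values, provenance=provenance,
                         raw_response_hash=hasher.hexdigest())
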