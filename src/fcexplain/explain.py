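"""Natural-language rendering of counterfactual edge changes.

Each counterfactual candidate becomes one intervention "step" — the set of
connectivity changes that would move the subject's predicted class to the
target.  Steps are ranked by feasibility: fewest edges changed first, then
least total MAD-normalized change.  A text-generation provider can be
asked to phrase the summary; when it is unreachable or returns malformed
output, a deterministic rule-based template produces the report instead,
so a report is always available offline.

Reports are research output, not clinical advice, and say so.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .counterfactual import CounterfactualSet
from .llm import ProviderConfig, make_provider

logger = logging.getLogger(__name__)

DISCLAIMER = (
    "Research use only: these model-derived connectivity adjustments are "
    "exploratory and are not clinical recommendations."
)


@dataclass
class ExplanationRequest:
    """Inputs to explanation: original edge values and per-candidate diffs."""

    edge_names: tuple[str, ...]
    original: np.ndarray
    candidate_diffs: list[list[tuple[int, float, float]]]  # (edge idx, before, after)
    audience: str = "clinician"  # clinician | patient

    def __post_init__(self) -> None:
        self.edge_names = tuple(self.edge_names)
        self.original = np.asarray(self.original, float)
        q = len(self.edge_names)
        for diffs in self.candidate_diffs:
            for j, _, _ in diffs:
                if not 0 <= j < q:
                    raise ValueError(f"diff references unknown edge index {j}")

    @classmethod
    def from_counterfactuals(
        cls,
        cf_set: CounterfactualSet,
        edge_names: tuple[str, ...] | list[str],
        audience: str = "clinician",
        valid_only: bool = True,
    ) -> "ExplanationRequest":
        idx = range(cf_set.candidates.shape[0])
        diffs = [
            cf_set.diffs(l)
            for l in idx
            if (not valid_only) or cf_set.validity[l]
        ]
        return cls(
            edge_names=tuple(edge_names), original=cf_set.original.copy(),
            candidate_diffs=diffs, audience=audience,
        )


@dataclass
class ExplanationStep:
    candidate: int
    edges: list[tuple[str, float, float]]  # (edge name, before, after)
    n_changes: int
    total_normalized_change: float

    def describe(self) -> str:
        if not self.edges:
            return "no change required"
        parts = []
        for name, before, after in self.edges:
            verb = "increase" if after > before else "decrease"
            parts.append(
                f"{verb} connectivity between {name.replace('-', ' and ')} "
                f"from {before:+.3f} to {after:+.3f}"
            )
        return "; ".join(parts)


@dataclass
class ExplanationReport:
    summary: str
    steps: list[ExplanationStep]
    provenance: str  # llm | template

    def __str__(self) -> str:
        lines = [self.summary, ""]
        for rank, step in enumerate(self.steps, 1):
            lines.append(f"Step {rank} (option {step.candidate + 1}): {step.describe()}")
        lines += ["", DISCLAIMER]
        return "\n".join(lines)


def _make_steps(req: ExplanationRequest) -> list[ExplanationStep]:
    steps = []
    for l, diffs in enumerate(req.candidate_diffs):
        edges = [(req.edge_names[j], before, after) for j, before, after in diffs]
        total = sum(abs(after - before) for _, before, after in edges)
        steps.append(ExplanationStep(
            candidate=l, edges=edges, n_changes=len(edges),
            total_normalized_change=total,
        ))
    steps.sort(key=lambda s: (s.n_changes, s.total_normalized_change, s.candidate))
    return steps


def build_explanation_prompt(req: ExplanationRequest) -> str:
    """Deterministic prompt embedding originals, all diffs, and ranking
    instructions."""
    if not req.candidate_diffs:
        raise ValueError("need at least one candidate")
    audience = (
        "a clinician" if req.audience == "clinician" else "a patient, in plain words"
    )
    lines = [
        "A classifier separates normal controls from schizophrenia patients "
        "using functional connectivity (FC) strengths between brain regions.",
        "For one patient, the counterfactual analysis found alternative FC "
        "profiles the classifier labels as normal. Explain, for "
        f"{audience}, what each option changes, then rank the options by "
        "effectiveness and feasibility (fewest, smallest changes first).",
        "",
        "Original FC values:",
    ]
    referenced = sorted({j for diffs in req.candidate_diffs for j, _, _ in diffs})
    for j in referenced:
        lines.append(f"- {req.edge_names[j]}: {req.original[j]:+.3f}")
    for l, diffs in enumerate(req.candidate_diffs, 1):
        lines.append("")
        lines.append(f"Option {l}:")
        if not diffs:
            lines.append("- no change required")
        for j, before, after in diffs:
            lines.append(
                f"- {req.edge_names[j]}: {before:+.3f} -> {after:+.3f}"
            )
    lines += [
        "",
        "Output format: one line per option, 'Rank <r>: Option <l>: "
        "<explanation>', best option first.",
    ]
    return "\n".join(lines)


def template_explanation(req: ExplanationRequest) -> ExplanationReport:
    """Deterministic rule-based report; the offline fallback path."""
    steps = _make_steps(req)
    n = len(steps)
    summary = (
        f"The model identified {n} candidate intervention option(s) that "
        "would move this subject's predicted class to normal control. "
        "Options are ranked by feasibility: fewest edges changed, then "
        "smallest total connectivity change."
    )
    return ExplanationReport(summary=summary, steps=steps, provenance="template")


def llm_explanation(
    req: ExplanationRequest, config: ProviderConfig
) -> ExplanationReport:
    """Ask the provider to phrase the report; fall back to the template.

    On success the verbatim response becomes the summary.  If the response
    does not follow the requested structure, the template ranking is
    attached alongside the raw text; on provider failure the pure template
    report is returned with a logged notice.
    """
    prompt = build_explanation_prompt(req)
    try:
        provider = make_provider(config)
        response = provider.complete(prompt)
    except Exception as e:  # provider trouble must never block a report
        logger.warning("explanation provider failed (%s); using template", e)
        return template_explanation(req)
    steps = _parse_ranked_steps(response, req)
    if steps is None:
        logger.warning("unparseable provider response; attaching template ranking")
        steps = _make_steps(req)
    return ExplanationReport(summary=response, steps=steps, provenance="llm")


def _parse_ranked_steps(text: str, req: ExplanationRequest):
    """Extract 'Rank r: Option l: ...' lines; None if structure is absent."""
    import re

    pattern = re.compile(r"Rank\s*(\d+)\s*:\s*Option\s*(\d+)", re.IGNORECASE)
    hits = pattern.findall(text)
    if not hits:
        return None
    by_rank = sorted((int(r), int(l) - 1) for r, l in hits)
    base = {s.candidate: s for s in _make_steps(req)}
    steps = []
    for _, cand in by_rank:
        if cand in base:
            steps.append(base[cand])
    return steps or None
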