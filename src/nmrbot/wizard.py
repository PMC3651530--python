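"""Interactive setup wizard: the manual-input twin of the STAR manifest.

A linear sequence of prompts collects the same information the manifest
carries — water standard, per-sample identity, then the optional behaviour
switches — validating each entry as it is given.  ``back`` re-opens the
previous step with the earlier answer as its default, ``quit`` aborts
cleanly, and a final review screen gates emission.  The emitted manifest
re-parses to exactly the returned config, so a wizard session is replayable
later in text-file mode.

The prompt channel is an abstract request/response contract: tests drive it
with scripted answers, the CLI with a terminal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

from .audit import AuditTrail
from .errors import WizardAborted
from .manifest import (
    RACK_PATTERN,
    AdaptationRule,
    FOLDER_TOKENS,
    RunConfig,
    SampleSpec,
    SeriesOptions,
    validate_config,
    write_manifest,
)
from .profile import InstrumentProfile, default_profile

__all__ = [
    "PromptChannel",
    "ScriptedChannel",
    "ConsoleChannel",
    "WizardState",
    "run_wizard",
    "review_and_emit",
]

BACK = "back"
QUIT = "quit"


class PromptChannel(Protocol):
    def ask(self, prompt: str, default: str | None = None) -> str: ...
    def say(self, text: str) -> None: ...


class ScriptedChannel:
    """Replays a fixed list of answers; used for tests and batch setup."""

    def __init__(self, answers: list[str]):
        self.answers = list(answers)
        self.transcript: list[tuple[str, str]] = []

    def ask(self, prompt: str, default: str | None = None) -> str:
        if not self.answers:
            raise AssertionError(f"script exhausted at prompt: {prompt!r}")
        raw = self.answers.pop(0)
        if raw == "" and default is not None:
            raw = default
        self.transcript.append((prompt, raw))
        return raw

    def say(self, text: str) -> None:
        self.transcript.append(("<say>", text))


class ConsoleChannel:
    """Terminal prompt channel used by the command-line interface."""

    def __init__(self, echo=None, prompt=None):
        import click

        self._echo = echo or click.echo
        self._prompt = prompt or (
            lambda text, default: click.prompt(
                text, default=default if default is not None else "",
                show_default=default is not None,
            )
        )

    def ask(self, prompt: str, default: str | None = None) -> str:
        return str(self._prompt(prompt, default))

    def say(self, text: str) -> None:
        self._echo(text)


@dataclass
class WizardState:
    """Progress through the step sequence; history makes ``back`` cheap."""

    step_index: int = 0
    history: dict[str, str] = field(default_factory=dict)
    rejections: list[tuple[str, str, str]] = field(default_factory=list)
    partial_config: RunConfig | None = None


@dataclass(frozen=True)
class _Step:
    id: str
    prompt: str
    validate: object  # callable(raw, answers) -> canonical str, or raises ValueError
    default: str | None = None


def _yes_no(raw: str, _answers) -> str:
    low = raw.strip().lower()
    if low in ("y", "yes", "true", "1"):
        return "yes"
    if low in ("n", "no", "false", "0"):
        return "no"
    raise ValueError("please answer yes or no")


def _positive_int(raw: str, _answers) -> str:
    try:
        value = int(raw)
    except ValueError:
        raise ValueError(f"{raw!r} is not an integer") from None
    if value < 1:
        raise ValueError("value must be >= 1")
    return str(value)


_RULE_RE = re.compile(
    r"^\s*(?P<src>\S+)\s+(?P<nuc>\S+)\s*->\s*(?P<targets>[^@]+?)\s*@\s*(?P<dim>\d+)\s*$"
)


def _parse_rules(raw: str) -> tuple[AdaptationRule, ...]:
    if raw.strip().lower() in ("", "none", "no"):
        return ()
    rules = []
    for chunk in raw.split(";"):
        m = _RULE_RE.match(chunk)
        if not m:
            raise ValueError(
                f"cannot parse rule {chunk.strip()!r}; expected "
                "'SOURCE NUCLEUS -> TARGET1,TARGET2 @ DIM'"
            )
        rules.append(
            AdaptationRule(
                source_experiment=m["src"],
                source_nucleus=m["nuc"],
                target_experiments=tuple(
                    t.strip() for t in m["targets"].split(",") if t.strip()
                ),
                target_dimension=int(m["dim"]),
            )
        )
    return tuple(rules)


def _build_steps(answers: dict[str, str], profile: InstrumentProfile) -> list[_Step]:
    """The full step list implied by the answers so far (dynamic: sample
    detail steps appear once the sample count is known)."""

    def identity(raw, _answers):
        if not raw.strip():
            raise ValueError("a value is required")
        return raw.strip()

    def optional(raw, _answers):
        return raw.strip()

    def solvent(raw, _answers):
        value = raw.strip()
        if value not in profile.solvents:
            raise ValueError(
                f"unknown solvent {value!r}; known: "
                + ", ".join(sorted(profile.solvents))
            )
        return value

    def rack_validator(own_key):
        def rack(raw, answers_now):
            value = raw.strip().upper()
            if not RACK_PATTERN.fullmatch(value):
                raise ValueError(f"{raw!r} is not a slot code like A1")
            taken = [
                v
                for k, v in answers_now.items()
                if k.endswith("_rack") and v == value and k != own_key
            ]
            if taken:
                raise ValueError(f"rack position {value} is already assigned")
            return value

        return rack

    def experiments(raw, _answers):
        names = tuple(p.strip() for p in raw.split(",") if p.strip())
        if not names:
            raise ValueError("list at least one experiment parameter set")
        return ",".join(names)

    def folder(raw, _answers):
        value = raw.strip()
        if not any("{" + t + "}" in value for t in FOLDER_TOKENS):
            raise ValueError(
                f"template needs at least one token from {FOLDER_TOKENS}"
            )
        return value

    def shim(raw, _answers):
        value = raw.strip()
        if value not in profile.shim_routines:
            raise ValueError(
                f"unknown shim routine {value!r}; advertised: "
                + ", ".join(sorted(profile.shim_routines))
            )
        return value

    def rules(raw, _answers):
        _parse_rules(raw)  # raises on malformed input
        return raw.strip() or "none"

    steps = [
        _Step("water_standard",
              "Include a water standard sample for 3D shimming? (yes/no)",
              _yes_no, "no"),
    ]
    if answers.get("water_standard") == "yes":
        steps.append(_Step("water_rack",
                           "Rack position of the water standard",
                           rack_validator("water_rack"), "A1"))
    steps.append(_Step("n_samples", "Number of samples", _positive_int))
    n = int(answers.get("n_samples", "0") or "0")
    for i in range(1, n + 1):
        steps += [
            _Step(f"sample_{i}_name", f"Sample {i} name", identity),
            _Step(f"sample_{i}_solvent",
                  f"Sample {i} solvent ({', '.join(sorted(profile.solvents))})",
                  solvent),
            _Step(f"sample_{i}_rack", f"Sample {i} rack position",
                  rack_validator(f"sample_{i}_rack")),
            _Step(f"sample_{i}_experiments",
                  f"Sample {i} experiment parameter sets (comma-separated)",
                  experiments),
        ]
    steps.append(_Step("folder_format", "Sample folder name format",
                       folder, "{name}_{index}"))
    for i in range(1, n + 1):
        steps.append(_Step(f"sample_{i}_notes",
                           f"Sample {i} condition notes (blank for none)",
                           optional, ""))
    for i in range(1, n + 1):
        steps.append(_Step(f"sample_{i}_ns",
                           f"Sample {i} NS multiplier", _positive_int, "1"))
    steps += [
        _Step("adaptive_sw",
              "Adaptive SW rules ('SRC NUC -> TGT @ DIM; ...' or 'none')",
              rules, "none"),
        _Step("use_prosol", "Load pulse length/power from PROSOL? (yes/no)",
              _yes_no, "no"),
        _Step("find_solvent_offset",
              "Detect solvent peak and set offsets per sample? (yes/no)",
              _yes_no, "no"),
        _Step("tune_match", "Tune and match for each sample? (yes/no)",
              _yes_no, "no"),
        _Step("shim_command",
              "Shim routine (" + ", ".join(sorted(profile.shim_routines)) + ")",
              shim, "1d-quick"),
        _Step("use_gain_optimization",
              "Optimize receiver gain per experiment? (yes/no)", _yes_no, "no"),
    ]
    return steps


def _config_from_answers(
    answers: dict[str, str], profile_name: str
) -> RunConfig:
    samples: list[SampleSpec] = []
    if answers.get("water_standard") == "yes":
        samples.append(
            SampleSpec(
                name="water_standard",
                solvent="H2O+D2O",
                rack_position=answers["water_rack"],
                experiment_sets=(),
                is_water_standard=True,
            )
        )
    n = int(answers["n_samples"])
    for i in range(1, n + 1):
        notes = answers.get(f"sample_{i}_notes", "").strip()
        samples.append(
            SampleSpec(
                name=answers[f"sample_{i}_name"],
                solvent=answers[f"sample_{i}_solvent"],
                rack_position=answers[f"sample_{i}_rack"],
                experiment_sets=tuple(
                    answers[f"sample_{i}_experiments"].split(",")
                ),
                ns_multiplier=int(answers.get(f"sample_{i}_ns", "1")),
                condition_notes=notes or None,
            )
        )
    options = SeriesOptions(
        use_water_standard=answers.get("water_standard") == "yes",
        folder_name_format=answers.get("folder_format", "{name}_{index}"),
        use_prosol=answers.get("use_prosol") == "yes",
        find_solvent_offset=answers.get("find_solvent_offset") == "yes",
        tune_match_each_sample=answers.get("tune_match") == "yes",
        shim_command=answers.get("shim_command", "1d-quick"),
        use_gain_optimization=answers.get("use_gain_optimization") == "yes",
        sw_adaptation=_parse_rules(answers.get("adaptive_sw", "none")),
    )
    return RunConfig(samples=tuple(samples), options=options,
                     instrument_profile=profile_name)


def _summary(config: RunConfig) -> str:
    lines = ["--- Review ---"]
    for i, s in enumerate(config.samples, 1):
        tag = " [water standard]" if s.is_water_standard else ""
        exps = ", ".join(s.experiment_sets) or "(shimming only)"
        lines.append(f"{i}. {s.name}{tag}  {s.solvent}  rack {s.rack_position}  "
                     f"NSx{s.ns_multiplier}  -> {exps}")
    o = config.options
    lines.append(
        f"options: folder={o.folder_name_format!r} prosol={o.use_prosol} "
        f"solvent_offset={o.find_solvent_offset} tune={o.tune_match_each_sample} "
        f"shim={o.shim_command!r} gain_opt={o.use_gain_optimization} "
        f"adaptive_sw={len(o.sw_adaptation)} rule(s)"
    )
    return "\n".join(lines)


def run_wizard(
    channel: PromptChannel,
    profile: InstrumentProfile | None = None,
    audit: AuditTrail | None = None,
) -> RunConfig:
    """Drive the prompt sequence to a validated RunConfig.

    An invalid entry repeats its step with an explanation (never aborts);
    ``back`` steps to the previous prompt with the earlier answer as
    default; ``quit`` raises :class:`WizardAborted`.  The returned config
    always passes validation — the final review step refuses to confirm
    otherwise.
    """
    profile = profile or default_profile()
    state = WizardState()

    while True:
        steps = _build_steps(state.history, profile)
        if state.step_index >= len(steps):
            config = _config_from_answers(state.history, profile.name)
            report = validate_config(config, profile=profile)
            channel.say(_summary(config))
            if not report.runnable:
                channel.say(str(report))
                if audit:
                    audit.warning("wizard", "review rejected an invalid setup")
                state.step_index = len(steps) - 1
                continue
            answer = channel.ask("Confirm setup? (yes/back/quit)", "yes").strip().lower()
            if answer == QUIT:
                raise WizardAborted("setup abandoned at review")
            if answer in (BACK, "no"):
                state.step_index = len(steps) - 1
                continue
            state.partial_config = config
            if audit:
                audit.info("wizard", "setup confirmed",
                           {"samples": len(config.samples),
                            "rejected_entries": len(state.rejections)})
            from dataclasses import replace as _replace

            return _replace(config, validation=report)

        step = steps[state.step_index]
        default = state.history.get(step.id, step.default)
        raw = channel.ask(step.prompt, default)
        command = raw.strip().lower()
        if command == QUIT:
            raise WizardAborted(f"setup abandoned at step {step.id!r}")
        if command == BACK:
            state.step_index = max(0, state.step_index - 1)
            continue
        try:
            state.history[step.id] = step.validate(raw, state.history)
        except ValueError as exc:
            channel.say(f"invalid entry: {exc}")
            state.rejections.append((step.id, raw, str(exc)))
            if audit:
                audit.warning("wizard", f"rejected entry at {step.id}: {exc}",
                              {"value": raw})
            continue
        state.step_index += 1


def review_and_emit(
    config: RunConfig,
    path: str | Path,
    channel: PromptChannel,
    profile: InstrumentProfile | None = None,
) -> Path | None:
    """Show the final review and, on confirmation, write the STAR manifest.

    The emitted file re-parses to a config equal to ``config``, so the
    session can be replayed in text-file mode.  Declining writes nothing
    and returns None (the caller may re-open the wizard).
    """
    channel.say(_summary(config))
    answer = channel.ask(
        f"Write manifest to {path} and begin acquisition? (yes/no)", "yes"
    )
    if answer.strip().lower() not in ("y", "yes"):
        return None
    text = write_manifest(config, profile=profile)
    out = Path(path)
    out.write_text(text, encoding="utf-8")
    return out
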