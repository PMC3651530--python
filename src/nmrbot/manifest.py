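"""STAR-format sample-series manifests: parse, validate, emit.

The manifest is the text-file input mode of the acquisition setup: one
``data_`` block holding flat ``_series.<key>`` tags for series-wide options,
an optional ``_adapt.*`` loop for adaptive spectral-width rules, and a
``_sample.*`` loop with one row per sample in acquisition order.  The dialect
is deliberately narrow — no save frames, no multi-block files — so that
``parse_manifest(write_manifest(cfg))`` is the identity on valid configs.

Example manifest::

    data_series

    _series.use_water_standard   yes
    _series.shim_command         3d

    loop_
       _sample.name
       _sample.solvent
       _sample.rack
       _sample.experiments
       _sample.ns_multiplier
       _sample.notes
       _sample.water_standard
       water  H2O+D2O  A1  .                1  .            yes
       s1     D2O      A2  PROTON,C13CPD    4  'pH 7.4'     no

Values containing whitespace are quoted; ``.`` denotes an absent value.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .errors import ManifestSyntaxError, ManifestValidationError
from .profile import InstrumentProfile, default_profile

__all__ = [
    "SampleSpec",
    "SeriesOptions",
    "AdaptationRule",
    "RunConfig",
    "ValidationIssue",
    "ValidationReport",
    "parse_manifest",
    "write_manifest",
    "validate_config",
]

RACK_PATTERN = re.compile(r"[A-Z][1-9][0-9]?")

FOLDER_TOKENS = ("name", "index", "date", "solvent", "rack")

#: documented defaults when series options are absent from a manifest
DEFAULT_FOLDER_FORMAT = "{name}_{index}"
DEFAULT_SHIM_COMMAND = "1d-quick"


@dataclass(frozen=True)
class AdaptationRule:
    """Route an observed 1D peak range into later experiments' windows.

    ``source_experiment`` names the 1D parameter set whose picked peaks
    define the observable shift range; after it completes, every experiment
    in ``target_experiments`` has dimension ``target_dimension`` (1-based)
    given the adapted spectral width and centered offset.
    """

    source_experiment: str
    source_nucleus: str
    target_experiments: tuple[str, ...]
    target_dimension: int


@dataclass(frozen=True)
class SampleSpec:
    """One sample's identity and per-sample acquisition choices."""

    name: str
    solvent: str
    rack_position: str
    experiment_sets: tuple[str, ...] = ()
    ns_multiplier: int = 1
    condition_notes: str | None = None
    is_water_standard: bool = False


@dataclass(frozen=True)
class SeriesOptions:
    """Series-wide optional behaviour; defaults are the minimal run."""

    use_water_standard: bool = False
    folder_name_format: str = DEFAULT_FOLDER_FORMAT
    use_prosol: bool = False
    find_solvent_offset: bool = False
    tune_match_each_sample: bool = False
    shim_command: str = DEFAULT_SHIM_COMMAND
    use_gain_optimization: bool = False
    sw_adaptation: tuple[AdaptationRule, ...] = ()


@dataclass(frozen=True)
class RunConfig:
    """The validated series description driving one acquisition run."""

    samples: tuple[SampleSpec, ...]
    options: SeriesOptions = SeriesOptions()
    instrument_profile: str = "default"
    #: validation report recorded before acquisition; not part of identity
    validation: "ValidationReport | None" = field(
        default=None, compare=False, repr=False
    )


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "fatal" | "warning"
    sample: str | None
    message: str

    def __str__(self) -> str:
        where = f" [sample {self.sample}]" if self.sample else ""
        return f"{self.severity.upper()}{where}: {self.message}"


@dataclass(frozen=True)
class ValidationReport:
    issues: tuple[ValidationIssue, ...]

    @property
    def fatal(self) -> tuple[ValidationIssue, ...]:
        return tuple(i for i in self.issues if i.severity == "fatal")

    @property
    def warnings(self) -> tuple[ValidationIssue, ...]:
        return tuple(i for i in self.issues if i.severity == "warning")

    @property
    def runnable(self) -> bool:
        return not self.fatal

    def __str__(self) -> str:
        if not self.issues:
            return "OK: no issues"
        return "\n".join(str(i) for i in self.issues)


# ---------------------------------------------------------------------------
# tokenizer


@dataclass(frozen=True)
class _Token:
    value: str | None
    quoted: bool

    @property
    def is_tag(self) -> bool:
        return (
            not self.quoted
            and self.value is not None
            and self.value.startswith("_")
        )

    def keyword(self) -> str:
        """Lower-cased value for structural keywords; quoted tokens are
        always data, never keywords."""
        if self.quoted or self.value is None:
            return ""
        return self.value.lower()


def _tokenize_line(line: str, lineno: int) -> list[_Token]:
    """Split one manifest line into values, honouring quotes and comments.

    Unquoted ``.`` maps to None (absent value).  A ``#`` starting a token
    begins a comment.  Quoted values may contain whitespace and the other
    quote character; quoting also shields values that would otherwise look
    like tags or keywords.
    """
    tokens: list[_Token] = []
    i, n = 0, len(line)
    while i < n:
        while i < n and line[i].isspace():
            i += 1
        if i >= n or line[i] == "#":
            break
        if line[i] in "'\"":
            quote = line[i]
            j = line.find(quote, i + 1)
            while j != -1 and j + 1 < n and not line[j + 1].isspace():
                j = line.find(quote, j + 1)
            if j == -1:
                raise ManifestSyntaxError("unterminated quoted value", lineno)
            tokens.append(_Token(line[i + 1 : j], True))
            i = j + 1
        else:
            j = i
            while j < n and not line[j].isspace():
                j += 1
            tok = line[i:j]
            tokens.append(_Token(None if tok == "." else tok, False))
            i = j
    return tokens


def _needs_quoting(value: str) -> bool:
    if value == "" or value == ".":
        return True
    if any(c.isspace() for c in value):
        return True
    if value[0] in "_#'\"$[]":
        return True
    return value.lower() in ("loop_", "stop_") or value.lower().startswith("data_")


def _quote(value: str | None) -> str:
    if value is None:
        return "."
    if not _needs_quoting(value):
        return value
    if "'" not in value:
        return f"'{value}'"
    return f'"{value}"'


def _parse_bool(raw: str, tag: str, lineno: int) -> bool:
    low = raw.lower()
    if low in ("yes", "true", "1", "on"):
        return True
    if low in ("no", "false", "0", "off"):
        return False
    raise ManifestSyntaxError(f"tag {tag}: expected yes/no, got {raw!r}", lineno)


def _split_list(cell: str | None) -> tuple[str, ...]:
    if cell is None or cell == "":
        return ()
    return tuple(p.strip() for p in cell.split(",") if p.strip())


# ---------------------------------------------------------------------------
# parsing

_SERIES_BOOL_TAGS = {
    "use_water_standard",
    "use_prosol",
    "find_solvent_offset",
    "tune_match_each_sample",
    "use_gain_optimization",
}

_SAMPLE_TAGS = (
    "_sample.name",
    "_sample.solvent",
    "_sample.rack",
    "_sample.experiments",
    "_sample.ns_multiplier",
    "_sample.notes",
    "_sample.water_standard",
)

_ADAPT_TAGS = (
    "_adapt.source_experiment",
    "_adapt.source_nucleus",
    "_adapt.target_experiments",
    "_adapt.target_dimension",
)


def parse_manifest(
    text: str, profile: InstrumentProfile | None = None
) -> RunConfig:
    """Parse and validate a STAR manifest, returning a runnable RunConfig.

    Raises :class:`ManifestSyntaxError` on malformed structure (naming the
    line) and :class:`ManifestValidationError` on semantic problems (the
    attached report lists *every* fatal issue, not just the first).  Sample
    order in the result equals row order in the file.  Series options absent
    from the file take their documented defaults.
    """
    if not text or not text.strip():
        raise ManifestSyntaxError("empty manifest", 1)

    lines = text.splitlines()
    series_tags: dict[str, tuple[str, int]] = {}
    unknown_tags: list[str] = []
    sample_rows: list[dict[str, str | None]] = []
    adapt_rows: list[dict[str, str | None]] = []
    saw_data_block = False

    i = 0
    nlines = len(lines)
    while i < nlines:
        lineno = i + 1
        tokens = _tokenize_line(lines[i], lineno)
        if not tokens:
            i += 1
            continue
        head = tokens[0]
        keyword = head.keyword()
        if keyword.startswith("data_"):
            if saw_data_block:
                raise ManifestSyntaxError(
                    "multiple data blocks are not supported", lineno
                )
            saw_data_block = True
            i += 1
        elif keyword == "loop_":
            i, rows, header = _parse_loop(lines, i + 1)
            if all(t.startswith("_sample.") for t in header):
                sample_rows.extend(rows)
            elif all(t.startswith("_adapt.") for t in header):
                adapt_rows.extend(rows)
            else:
                raise ManifestSyntaxError(
                    f"loop mixes tag families: {header}", lineno
                )
        elif head.is_tag:
            tag = head.value
            if len(tokens) < 2:
                raise ManifestSyntaxError(f"tag {tag} has no value", lineno)
            if len(tokens) > 2:
                raise ManifestSyntaxError(
                    f"tag {tag} has multiple values", lineno
                )
            value = tokens[1].value
            if tag.startswith("_series."):
                series_tags[tag[len("_series.") :]] = (
                    "" if value is None else value,
                    lineno,
                )
            else:
                unknown_tags.append(tag)
            i += 1
        elif keyword == "stop_":
            raise ManifestSyntaxError("stop_ outside a loop", lineno)
        else:
            raise ManifestSyntaxError(
                f"unexpected token {head.value!r}", lineno
            )

    config, extra_issues = _build_config(
        series_tags, adapt_rows, sample_rows, unknown_tags
    )
    report = validate_config(config, profile=profile, extra=extra_issues)
    if not report.runnable:
        raise ManifestValidationError(report)
    return replace(config, validation=report)


def _parse_loop(lines, start):
    """Parse loop header tags then data rows until stop_/EOF/next section."""
    header: list[str] = []
    i = start
    while i < len(lines):
        tokens = _tokenize_line(lines[i], i + 1)
        if not tokens:
            i += 1
            continue
        if tokens[0].is_tag:
            if len(tokens) != 1:
                raise ManifestSyntaxError(
                    "loop header tag line must hold one tag", i + 1
                )
            header.append(tokens[0].value)
            i += 1
        else:
            break
    if not header:
        raise ManifestSyntaxError("loop_ with no tags", start + 1)

    rows: list[dict[str, str | None]] = []
    while i < len(lines):
        lineno = i + 1
        tokens = _tokenize_line(lines[i], lineno)
        if not tokens:
            i += 1
            continue
        first = tokens[0]
        if first.keyword() == "stop_":
            i += 1
            break
        if (
            first.is_tag
            or first.keyword() == "loop_"
            or first.keyword().startswith("data_")
        ):
            break  # loop terminated implicitly by the next section
        if len(tokens) != len(header):
            raise ManifestSyntaxError(
                f"loop row has {len(tokens)} values for {len(header)} tags",
                lineno,
            )
        rows.append(dict(zip(header, (t.value for t in tokens))))
        i += 1
    return i, rows, header


def _build_config(series_tags, adapt_rows, sample_rows, unknown_tags):
    """Assemble a RunConfig from raw parsed pieces; defer semantics to
    validate_config but collect structural issues found on the way."""
    issues: list[ValidationIssue] = []
    for tag in unknown_tags:
        issues.append(ValidationIssue("warning", None, f"unknown tag {tag}"))

    opts_kwargs: dict = {}
    instrument_profile = "default"
    for key, (raw, lineno) in series_tags.items():
        if key in _SERIES_BOOL_TAGS:
            opts_kwargs[key] = _parse_bool(raw, f"_series.{key}", lineno)
        elif key == "folder_name_format":
            opts_kwargs["folder_name_format"] = raw
        elif key == "shim_command":
            opts_kwargs["shim_command"] = raw
        elif key == "instrument_profile":
            instrument_profile = raw
        else:
            issues.append(
                ValidationIssue("warning", None, f"unknown tag _series.{key}")
            )

    rules = []
    for row in adapt_rows:
        dim_raw = row.get("_adapt.target_dimension")
        try:
            dim = int(dim_raw) if dim_raw is not None else 0
        except ValueError:
            dim = 0
            issues.append(
                ValidationIssue(
                    "fatal",
                    None,
                    f"adaptation rule target_dimension {dim_raw!r} not an integer",
                )
            )
        rules.append(
            AdaptationRule(
                source_experiment=row.get("_adapt.source_experiment") or "",
                source_nucleus=row.get("_adapt.source_nucleus") or "",
                target_experiments=_split_list(
                    row.get("_adapt.target_experiments")
                ),
                target_dimension=dim,
            )
        )
    if rules:
        opts_kwargs["sw_adaptation"] = tuple(rules)

    samples = []
    for idx, row in enumerate(sample_rows):
        name = row.get("_sample.name")
        missing = [
            tag
            for tag in ("_sample.name", "_sample.solvent", "_sample.rack")
            if row.get(tag) is None
        ]
        for tag in missing:
            issues.append(
                ValidationIssue(
                    "fatal",
                    name or f"row {idx + 1}",
                    f"missing required tag {tag}",
                )
            )
        ns_raw = row.get("_sample.ns_multiplier")
        try:
            ns_multiplier = 1 if ns_raw is None else int(ns_raw)
        except ValueError:
            ns_multiplier = 0
            issues.append(
                ValidationIssue(
                    "fatal",
                    name or f"row {idx + 1}",
                    f"ns_multiplier {ns_raw!r} is not an integer",
                )
            )
        ws_raw = row.get("_sample.water_standard")
        is_ws = (
            _parse_bool(ws_raw, "_sample.water_standard", 0)
            if ws_raw is not None
            else False
        )
        samples.append(
            SampleSpec(
                name=name or "",
                solvent=row.get("_sample.solvent") or "",
                rack_position=row.get("_sample.rack") or "",
                experiment_sets=_split_list(row.get("_sample.experiments")),
                ns_multiplier=ns_multiplier,
                condition_notes=row.get("_sample.notes"),
                is_water_standard=is_ws,
            )
        )

    config = RunConfig(
        samples=tuple(samples),
        options=SeriesOptions(**opts_kwargs),
        instrument_profile=instrument_profile,
    )
    return config, issues


# ---------------------------------------------------------------------------
# writing


def write_manifest(
    config: RunConfig, profile: InstrumentProfile | None = None
) -> str:
    """Emit a config as manifest text; the output re-parses to an equal
    config and a second write of the re-parse is byte-identical.

    Refuses an invalid config by raising :class:`ManifestValidationError`
    with the validation report.
    """
    report = validate_config(config, profile=profile)
    if not report.runnable:
        raise ManifestValidationError(report)

    o = config.options
    lines = ["data_nmrbot_series", ""]
    series = [
        ("use_water_standard", "yes" if o.use_water_standard else "no"),
        ("folder_name_format", o.folder_name_format),
        ("use_prosol", "yes" if o.use_prosol else "no"),
        ("find_solvent_offset", "yes" if o.find_solvent_offset else "no"),
        (
            "tune_match_each_sample",
            "yes" if o.tune_match_each_sample else "no",
        ),
        ("shim_command", o.shim_command),
        ("use_gain_optimization", "yes" if o.use_gain_optimization else "no"),
        ("instrument_profile", config.instrument_profile),
    ]
    width = max(len(k) for k, _ in series) + len("_series.") + 3
    for key, value in series:
        lines.append(f"{('_series.' + key).ljust(width)}{_quote(value)}")
    lines.append("")

    if o.sw_adaptation:
        lines.append("loop_")
        lines.extend(f"   {tag}" for tag in _ADAPT_TAGS)
        for rule in o.sw_adaptation:
            lines.append(
                "   "
                + "  ".join(
                    (
                        _quote(rule.source_experiment),
                        _quote(rule.source_nucleus),
                        _quote(",".join(rule.target_experiments)),
                        str(rule.target_dimension),
                    )
                )
            )
        lines.append("stop_")
        lines.append("")

    lines.append("loop_")
    lines.extend(f"   {tag}" for tag in _SAMPLE_TAGS)
    cells = [
        (
            _quote(s.name),
            _quote(s.solvent),
            _quote(s.rack_position),
            _quote(",".join(s.experiment_sets)) if s.experiment_sets else ".",
            str(s.ns_multiplier),
            _quote(s.condition_notes),
            "yes" if s.is_water_standard else "no",
        )
        for s in config.samples
    ]
    widths = [max(len(row[j]) for row in cells) for j in range(len(_SAMPLE_TAGS))]
    for row in cells:
        lines.append(
            "   " + "  ".join(c.ljust(w) for c, w in zip(row, widths)).rstrip()
        )
    lines.append("stop_")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# validation


def validate_config(
    config: RunConfig,
    profile: InstrumentProfile | None = None,
    extra: list[ValidationIssue] | None = None,
) -> ValidationReport:
    """Check every config invariant; never raises — reports.

    The config is runnable iff the report has no fatal issue.  Each issue
    carries a severity, the offending sample (when applicable) and a message.
    """
    profile = profile or default_profile()
    issues: list[ValidationIssue] = list(extra or [])

    def fatal(sample, msg):
        issues.append(ValidationIssue("fatal", sample, msg))

    def warn(sample, msg):
        issues.append(ValidationIssue("warning", sample, msg))

    if not config.samples:
        fatal(None, "series contains no samples")

    seen_names: set[str] = set()
    seen_racks: set[str] = set()
    for s in config.samples:
        if not s.name:
            fatal(s.name or "?", "sample name is empty")
        elif s.name in seen_names:
            fatal(s.name, f"duplicate sample name {s.name!r}")
        seen_names.add(s.name)

        if s.solvent not in profile.solvents:
            fatal(
                s.name,
                f"unknown solvent {s.solvent!r}; known: "
                + ", ".join(sorted(profile.solvents)),
            )
        if not RACK_PATTERN.fullmatch(s.rack_position or ""):
            fatal(
                s.name,
                f"rack position {s.rack_position!r} does not match "
                "letter+number slot code (e.g. A1)",
            )
        elif s.rack_position in seen_racks:
            fatal(s.name, f"duplicate rack position {s.rack_position!r}")
        seen_racks.add(s.rack_position)

        if not s.experiment_sets and not s.is_water_standard:
            fatal(s.name, "no experiments listed (only a water standard may run none)")
        if s.ns_multiplier < 1:
            fatal(s.name, f"ns_multiplier must be >= 1, got {s.ns_multiplier}")
        for text_value in (s.name, s.condition_notes or ""):
            if "\n" in text_value or ("'" in text_value and '"' in text_value):
                fatal(s.name, "value contains characters the manifest cannot quote")

    ws = [s for s in config.samples if s.is_water_standard]
    if len(ws) > 1:
        fatal(None, "at most one water-standard sample is allowed")
    elif ws and config.samples and config.samples[0] is not ws[0]:
        fatal(ws[0].name, "the water-standard sample must be first in the series")

    o = config.options
    if not any("{" + t + "}" in o.folder_name_format for t in FOLDER_TOKENS):
        fatal(
            None,
            f"folder_name_format {o.folder_name_format!r} contains no "
            f"substitution token from {FOLDER_TOKENS}",
        )
    if o.shim_command not in profile.shim_routines:
        fatal(
            None,
            f"shim command {o.shim_command!r} not advertised by the backend; "
            + "known: " + ", ".join(sorted(profile.shim_routines)),
        )

    for rule in o.sw_adaptation:
        label = f"{rule.source_experiment}->{','.join(rule.target_experiments)}"
        if rule.target_dimension < 1:
            fatal(None, f"adaptation rule {label}: target_dimension must be >= 1")
        if not rule.source_experiment:
            fatal(None, f"adaptation rule {label}: empty source experiment")
        for target in rule.target_experiments:
            params = profile.parameter_sets.get(target)
            if params is None:
                warn(None, f"adaptation rule {label}: unknown target {target!r}")
            elif rule.target_dimension > params.dimensionality:
                fatal(
                    None,
                    f"adaptation rule {label}: target {target!r} has "
                    f"{params.dimensionality} dimension(s), rule wants "
                    f"dimension {rule.target_dimension}",
                )
        for s in config.samples:
            relevant = [t for t in rule.target_experiments if t in s.experiment_sets]
            if not relevant:
                continue
            if rule.source_experiment not in s.experiment_sets:
                fatal(
                    s.name,
                    f"adaptation rule {label}: source "
                    f"{rule.source_experiment!r} is not in the sample's "
                    "experiment list",
                )
                continue
            src_idx = s.experiment_sets.index(rule.source_experiment)
            for t in relevant:
                if s.experiment_sets.index(t) <= src_idx:
                    fatal(
                        s.name,
                        f"adaptation rule {label}: target {t!r} does not run "
                        "after its source",
                    )

    return ValidationReport(tuple(issues))
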