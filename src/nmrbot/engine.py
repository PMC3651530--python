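"""Series orchestration: prepare the instrument per sample, load and modify
parameter sets, run every experiment against a backend, and never let one
failure take down the series.

The engine is backend-agnostic: anything satisfying :class:`Backend`
(insert, eject, lock, tune_match, shim, acquire, optimize_gain, plus the
shim-routine and gain-ladder queries) can drive real or simulated hardware.

Parameter modifications are applied in a fixed order — PROSOL merge, NS
multiplier, solvent-offset substitution, adapted spectral width, receiver
gain — and every one of them is written to the per-experiment modification
ledger and the audit trail, so any difference between a stored parameter
set and the parameters actually acquired with is attributable to exactly
one recorded step.
"""

from __future__ import annotations

import json
import re
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

from .audit import AuditTrail
from .errors import (
    GainClippedAtMinimumError,
    InstrumentContractError,
    LockError,
    ManifestValidationError,
    NmrbotError,
    NoSolventPeakError,
    UnknownParameterSetError,
)
from .manifest import RunConfig, SampleSpec, validate_config
from .peaks import adapt_sw, apply_adaptation, find_solvent_offset, pick_peaks
from .profile import ExperimentParams, InstrumentProfile, default_profile
from .simulate import write_spectrum

__all__ = [
    "Backend",
    "Modification",
    "ExperimentOutcome",
    "SampleResult",
    "SeriesResult",
    "run_series",
    "load_parameter_set",
    "apply_ns_multiplier",
    "format_folder_name",
    "solvent_offset_prescan",
]


@runtime_checkable
class Backend(Protocol):
    """Instrument contract every spectrometer driver must satisfy."""

    profile: InstrumentProfile

    def insert(self, rack_position: str) -> None: ...
    def eject(self) -> None: ...
    def lock(self, solvent: str) -> None: ...
    def tune_match(self) -> None: ...
    def shim(self, command: str) -> float: ...
    def acquire(self, params: ExperimentParams, seed: int): ...
    def optimize_gain(self, params: ExperimentParams) -> float: ...

    @property
    def shim_routine_names(self) -> tuple[str, ...]: ...

    @property
    def gain_ladder(self) -> tuple[float, ...]: ...


@dataclass(frozen=True)
class Modification:
    """One audited change to a loaded parameter set."""

    kind: str  # prosol | ns_multiplier | solvent_offset | adapted_sw | gain
    detail: tuple[tuple[str, object], ...]  # sorted (field, value) pairs

    @classmethod
    def make(cls, kind: str, **detail) -> "Modification":
        return cls(kind, tuple(sorted(detail.items())))

    def as_dict(self) -> dict:
        return {"kind": self.kind, **dict(self.detail)}


@dataclass(frozen=True)
class ExperimentOutcome:
    parameter_set: str
    expno: int
    status: str  # completed | failed | skipped
    reason: str | None = None
    modifications: tuple[Modification, ...] = ()
    params: ExperimentParams | None = field(default=None, compare=False, repr=False)
    spectrum: object = field(default=None, compare=False, repr=False)
    folder: str | None = field(default=None, compare=False)
    elapsed: float = field(default=0.0, compare=False)


@dataclass(frozen=True)
class SampleResult:
    name: str
    status: str  # completed | skipped
    reason: str | None
    folder: str | None
    outcomes: tuple[ExperimentOutcome, ...]
    timings: dict = field(default_factory=dict, compare=False)
    final_shim_quality: float | None = field(default=None, compare=False)


@dataclass(frozen=True)
class SeriesResult:
    sample_results: tuple[SampleResult, ...]
    series_errors: tuple[str, ...]
    audit_path: str | None
    outdir: str | None
    audit_events: tuple = field(default=(), compare=False, repr=False)

    def outcome_table(self) -> list[tuple[str, str, int, str]]:
        """(sample, parameter set, expno, status) rows, in run order."""
        return [
            (s.name, o.parameter_set, o.expno, o.status)
            for s in self.sample_results
            for o in s.outcomes
        ]

    def counts(self) -> dict[str, int]:
        table = {"completed": 0, "failed": 0, "skipped": 0}
        for _, _, _, status in self.outcome_table():
            table[status] += 1
        return table

    def audit_signature(self) -> tuple:
        """Audit sequence with timestamps stripped, for replay comparison."""
        return tuple((e.scope, e.level, e.message) for e in self.audit_events)


# ---------------------------------------------------------------------------
# parameter-set handling


def load_parameter_set(
    name: str,
    library: dict[str, ExperimentParams],
    use_prosol: bool = False,
    profile: InstrumentProfile | None = None,
) -> tuple[ExperimentParams, list[Modification]]:
    """Fetch a named parameter set, optionally merging PROSOL pulse values.

    Returns a copy plus the modification records.  Raises
    :class:`UnknownParameterSetError` for a name not in the library (the
    engine turns this into a failed experiment and moves on).
    """
    stored = library.get(name)
    if stored is None:
        raise UnknownParameterSetError(f"no parameter set named {name!r}")
    params = replace(stored)
    mods: list[Modification] = []
    if use_prosol:
        profile = profile or default_profile()
        nucleus = params.dims[0].nucleus
        entry = profile.prosol.get(nucleus)
        if entry is not None:
            length, power = entry
            if (length, power) != (params.pulse_length, params.pulse_power):
                params = replace(params, pulse_length=length, pulse_power=power)
                mods.append(
                    Modification.make(
                        "prosol", nucleus=nucleus,
                        pulse_length=length, pulse_power=power,
                    )
                )
    return params, mods


def apply_ns_multiplier(
    params: ExperimentParams, multiplier: int
) -> tuple[ExperimentParams, list[Modification]]:
    """NS' = NS x multiplier; everything else untouched."""
    if multiplier < 1:
        raise ValueError("NS multiplier must be >= 1")
    if multiplier == 1:
        return params, []
    new = replace(params, ns=params.ns * multiplier)
    return new, [
        Modification.make("ns_multiplier", factor=multiplier, ns=new.ns)
    ]


_UNSAFE = re.compile(r"[^A-Za-z0-9._-]+")


def format_folder_name(
    sample: SampleSpec,
    template: str,
    index: int,
    date: str | None = None,
    existing: set[str] | None = None,
) -> str:
    """Render a folder-name template and make it a safe, unique path segment.

    Tokens: ``{name} {index} {date} {solvent} {rack}``.  Characters outside
    ``[A-Za-z0-9._-]`` collapse to underscores; a collision with ``existing``
    gets a numeric suffix (``_2``, ``_3``, ...).
    """
    rendered = template.format(
        name=sample.name,
        index=index,
        date=date or time.strftime("%Y%m%d"),
        solvent=sample.solvent,
        rack=sample.rack_position,
    )
    safe = _UNSAFE.sub("_", rendered).strip("._") or f"sample_{index}"
    if existing is not None:
        candidate, n = safe, 1
        while candidate in existing:
            n += 1
            candidate = f"{safe}_{n}"
        existing.add(candidate)
        return candidate
    return safe


def solvent_offset_prescan(
    backend: Backend,
    params_1h: ExperimentParams,
    seed: int,
    snr_threshold: float = 6.0,
) -> float | None:
    """Quick 1H 1D plus peak analysis to locate the dominant solvent line.

    Returns the offset (ppm) to substitute into every subsequent
    experiment's 1H dimension for this sample, or None when no peak clears
    the threshold (callers keep defaults and audit a warning).
    """
    spectrum = backend.acquire(params_1h, seed)
    peaks = pick_peaks(spectrum, snr_threshold)
    try:
        return find_solvent_offset(peaks)
    except NoSolventPeakError:
        return None


# ---------------------------------------------------------------------------
# series orchestration


def _skipped_sample(sample: SampleSpec, reason: str) -> SampleResult:
    outcomes = tuple(
        ExperimentOutcome(name, i + 1, "skipped", reason=reason)
        for i, name in enumerate(sample.experiment_sets)
    )
    return SampleResult(sample.name, "skipped", reason, None, outcomes)


def run_series(
    config: RunConfig,
    backend: Backend,
    outdir: str | Path | None,
    seed: int,
    series_name: str = "series",
    console=None,
    write_spectra: bool | None = None,
) -> SeriesResult:
    """Run a validated series against a backend; continue on error.

    Per sample: insert -> lock -> optional tune/match -> shim -> create
    folder -> for each experiment: load -> PROSOL -> NS multiplier ->
    solvent-offset substitution -> adapted SW -> gain -> acquire -> store,
    then apply any adaptation rule whose source just completed to the
    remaining queue.  A water-standard sample runs first and establishes
    converged three-dimensional shims that seed the rest of the series.

    Sample-level failures (insert/lock) skip the sample; experiment-level
    failures fail that experiment; both are audited and the series carries
    on.  Anything outside the instrument contract aborts the series with a
    fatal audit entry and a partial result.

    ``outdir=None`` runs fully in memory (no folders, no spectrum files).
    """
    profile = getattr(backend, "profile", None) or default_profile()
    report = config.validation or validate_config(config, profile=profile)
    if not report.runnable:
        raise ManifestValidationError(report)

    if write_spectra is None:
        write_spectra = outdir is not None
    series_dir: Path | None = None
    audit = AuditTrail(console=console)
    if outdir is not None:
        series_dir = Path(outdir) / series_name
        series_dir.mkdir(parents=True, exist_ok=True)
        audit.series_path = series_dir / "series_audit.txt"

    rng = np.random.default_rng(seed)

    def next_seed() -> int:
        return int(rng.integers(0, 2**31))

    library = profile.parameter_sets
    audit.info("series", f"series start: {len(config.samples)} sample(s)")
    results: list[SampleResult] = []
    series_errors: list[str] = []
    folder_names: set[str] = set()

    try:
        for index, sample in enumerate(config.samples, start=1):
            results.append(
                _run_sample(
                    sample, index, config, backend, profile, library,
                    series_dir, folder_names, audit, next_seed, write_spectra,
                )
            )
    except Exception as exc:  # unhandled backend fault: abort with partial result
        msg = f"series aborted by unhandled backend fault: {exc}"
        audit.fatal("series", msg)
        series_errors.append(msg)
        done = {r.name for r in results}
        for sample in config.samples:
            if sample.name not in done:
                results.append(_skipped_sample(sample, "series aborted"))

    counts = SeriesResult(tuple(results), (), None, None).counts()
    audit.info("series", f"series finished: {counts}")
    return SeriesResult(
        sample_results=tuple(results),
        series_errors=tuple(series_errors),
        audit_path=str(audit.series_path) if audit.series_path else None,
        outdir=str(series_dir) if series_dir else None,
        audit_events=tuple(audit.events),
    )


def _shim_to_convergence(backend: Backend, command: str, audit, scope) -> float:
    quality = None
    for _ in range(25):
        new = backend.shim(command)
        if quality is not None and abs(new - quality) < 1e-9:
            break
        quality = new
    audit.info(scope, f"shims converged with {command!r}",
               {"shim_quality": round(quality, 6)})
    return quality


def _run_sample(
    sample, index, config, backend, profile, library,
    series_dir, folder_names, audit, next_seed, write_spectra,
) -> SampleResult:
    opts = config.options
    scope = sample.name
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    def clock(step):
        nonlocal t0
        now = time.perf_counter()
        timings[step] = now - t0
        t0 = now

    # --- instrument preparation: failures here skip the whole sample
    try:
        backend.insert(sample.rack_position)
        clock("insert")
        audit.info(scope, f"inserted from rack {sample.rack_position}")
        backend.lock(sample.solvent)
        clock("lock")
        audit.info(scope, f"lock established on {sample.solvent}")
    except (InstrumentContractError, LockError) as exc:
        audit.error(scope, f"sample skipped: {exc}")
        return _skipped_sample(sample, str(exc))

    try:
        if opts.tune_match_each_sample:
            backend.tune_match()
            clock("tune_match")
            audit.info(scope, "probe tuned and matched")
    except InstrumentContractError as exc:
        audit.error(scope, f"tune/match failed, continuing untuned: {exc}")

    try:
        if sample.is_water_standard:
            command = "3d" if "3d" in backend.shim_routine_names else opts.shim_command
            quality = _shim_to_convergence(backend, command, audit, scope)
        else:
            quality = backend.shim(opts.shim_command)
            audit.info(scope, f"shimmed with {opts.shim_command!r}",
                       {"shim_quality": round(quality, 6)})
        clock("shim")
    except InstrumentContractError as exc:
        quality = None
        audit.error(scope, f"shim failed, continuing unshimmed: {exc}")

    # --- sample folder
    folder_path: Path | None = None
    folder = format_folder_name(
        sample, opts.folder_name_format, index, existing=folder_names
    )
    if series_dir is not None:
        folder_path = series_dir / folder
        folder_path.mkdir(parents=True, exist_ok=True)
        audit.open_sample(folder_path)
    audit.info(scope, f"sample folder {folder!r}")
    if sample.condition_notes:
        audit.info(scope, f"condition notes: {sample.condition_notes}")

    # --- optional solvent-offset pre-scan
    solvent_offset: float | None = None
    if opts.find_solvent_offset and sample.experiment_sets:
        prescan_params = library.get(profile.prescan_parameter_set)
        if prescan_params is None:
            audit.warning(scope, "no pre-scan parameter set; offsets kept")
        else:
            try:
                solvent_offset = solvent_offset_prescan(
                    backend, prescan_params, next_seed()
                )
            except (InstrumentContractError, NmrbotError) as exc:
                audit.error(scope, f"solvent pre-scan failed: {exc}")
            if solvent_offset is not None:
                audit.info(scope, "solvent offset detected",
                           {"offset_ppm": round(solvent_offset, 5)})
            else:
                audit.warning(
                    scope, "no solvent peak found; parameter-set offsets kept"
                )
        clock("solvent_prescan")

    # --- load the experiment queue
    queue: list[ExperimentParams | None] = []
    base_mods: list[list[Modification]] = []
    load_errors: list[str | None] = []
    for name in sample.experiment_sets:
        try:
            params, mods = load_parameter_set(
                name, library, use_prosol=opts.use_prosol, profile=profile
            )
        except UnknownParameterSetError as exc:
            queue.append(None)
            base_mods.append([])
            load_errors.append(str(exc))
            continue
        params, ns_mods = apply_ns_multiplier(params, sample.ns_multiplier)
        mods += ns_mods
        if solvent_offset is not None:
            for d, dim in enumerate(params.dims, start=1):
                if dim.nucleus == "1H" and dim.offset != solvent_offset:
                    params = params.with_dim(d, sw=dim.sw, offset=solvent_offset)
                    mods.append(
                        Modification.make(
                            "solvent_offset", dimension=d,
                            offset=round(solvent_offset, 6),
                        )
                    )
        queue.append(params)
        base_mods.append(list(mods))
        load_errors.append(None)

    adaptation_mods: dict[int, list[Modification]] = {}

    # --- run the experiments
    outcomes: list[ExperimentOutcome] = []
    for expno0, name in enumerate(sample.experiment_sets):
        expno = expno0 + 1
        exp_scope = f"{sample.name}/{expno}"
        params = queue[expno0]
        if params is None:
            audit.error(exp_scope, f"parameter set load failed: {load_errors[expno0]}")
            outcomes.append(
                ExperimentOutcome(name, expno, "failed", reason=load_errors[expno0])
            )
            continue
        mods = base_mods[expno0] + adaptation_mods.get(expno0, [])
        t_exp = time.perf_counter()
        try:
            if opts.use_gain_optimization and params.receiver_gain == "auto":
                try:
                    gain = backend.optimize_gain(params)
                except GainClippedAtMinimumError as exc:
                    gain = exc.min_gain
                    audit.warning(
                        exp_scope,
                        f"signal clips even at minimum gain; using {gain}",
                    )
                params = replace(params, receiver_gain=gain)
                mods.append(Modification.make("gain", receiver_gain=gain))
                audit.info(exp_scope, "receiver gain optimized",
                           {"receiver_gain": gain})
            spectrum = backend.acquire(params, next_seed())
        except (InstrumentContractError, NmrbotError) as exc:
            audit.error(exp_scope, f"experiment {name} failed: {exc}")
            outcomes.append(
                ExperimentOutcome(
                    name, expno, "failed", reason=str(exc),
                    modifications=tuple(mods),
                    elapsed=time.perf_counter() - t_exp,
                )
            )
            continue

        exp_folder = None
        if folder_path is not None and write_spectra:
            exp_dir = folder_path / str(expno)
            exp_dir.mkdir(exist_ok=True)
            write_spectrum(spectrum, exp_dir / "spectrum")
            (exp_dir / "params.json").write_text(
                json.dumps(_params_snapshot(params, mods), indent=1) + "\n"
            )
            exp_folder = str(exp_dir)
        audit.info(exp_scope, f"experiment {name} completed",
                   {"modifications": [m.as_dict() for m in mods]})
        outcomes.append(
            ExperimentOutcome(
                name, expno, "completed",
                modifications=tuple(mods), params=params,
                spectrum=spectrum, folder=exp_folder,
                elapsed=time.perf_counter() - t_exp,
            )
        )

        # --- adaptive spectral width from a just-completed 1D source
        for rule in opts.sw_adaptation:
            if rule.source_experiment != name or params.dimensionality != 1:
                continue
            if rule.source_nucleus and rule.source_nucleus != params.dims[0].nucleus:
                continue
            peaks = pick_peaks(spectrum)
            if not peaks.peaks:
                audit.warning(
                    exp_scope,
                    f"adaptation from {name}: no peaks found, defaults kept",
                )
                continue
            sw, offset = adapt_sw(peaks)
            tail = [q for q in queue[expno0 + 1 :] if q is not None]
            updated, touched = apply_adaptation(rule, (sw, offset), tail)
            it = iter(updated)
            for j in range(expno0 + 1, len(queue)):
                if queue[j] is not None:
                    queue[j] = next(it)
            present = set(touched)
            remaining = set(sample.experiment_sets[expno0 + 1 :])
            for target in rule.target_experiments:
                if target not in remaining:
                    audit.warning(
                        exp_scope,
                        f"adaptation target {target!r} not queued after {name}",
                    )
            for j in range(expno0 + 1, len(queue)):
                if queue[j] is not None and sample.experiment_sets[j] in present:
                    adaptation_mods.setdefault(j, []).append(
                        Modification.make(
                            "adapted_sw",
                            source=name,
                            dimension=rule.target_dimension,
                            sw=round(sw, 6),
                            offset=round(offset, 6),
                        )
                    )
            audit.info(
                exp_scope,
                f"adapted SW from {name} applied to {sorted(present)}",
                {"sw_ppm": round(sw, 6), "offset_ppm": round(offset, 6)},
            )

    clock("experiments")
    audit.close_sample()
    backend.eject()
    audit.info(scope, "sample ejected")
    return SampleResult(
        name=sample.name,
        status="completed",
        reason=None,
        folder=str(folder_path) if folder_path else folder,
        outcomes=tuple(outcomes),
        timings=timings,
        final_shim_quality=quality,
    )


def _params_snapshot(params: ExperimentParams, mods) -> dict:
    return {
        "parameter_set": params.parameter_set_name,
        "ns": params.ns,
        "receiver_gain": params.receiver_gain,
        "pulse_length_us": params.pulse_length,
        "pulse_power_db": params.pulse_power,
        "dims": [
            {
                "nucleus": d.nucleus,
                "sw_ppm": d.sw,
                "offset_ppm": d.offset,
                "points": d.points,
            }
            for d in params.dims
        ],
        "modifications": [m.as_dict() for m in mods],
    }
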