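"""Persisted working state for the CLI: original data, current data, step log.

A session is a directory holding the original spectral matrix (as loaded),
the current (cleaned) matrix, the optional response table, and an ordered
JSON log of applied steps with their parameters.  The contract is replay
determinism: re-applying the logged mutating steps to the original dataset
reproduces the current dataset byte-identically on export.  Analyses can
run from the current data (chained cleaning) or from the original data,
which resets the log to the single new step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigError, LookupError
from .noise_filter import NoiseSegment, apply_noise_filter
from .scan_qc import delete_samples
from .screening import remove_plots
from .spectral_io import (
    ResponseTable,
    SpectralDataset,
    export_dataset,
    load_responses,
    load_spectra,
)

_META = "session.json"
_LOG = "steplog.json"
_ORIGINAL = "original_spectra.csv"
_CURRENT = "current_spectra.csv"
_RESPONSES = "responses.csv"


@dataclass
class SessionState:
    root: Path
    samples_per_scan: int
    steps: list[dict]

    # -- creation / loading ---------------------------------------------
    @classmethod
    def create(
        cls,
        root: str | Path,
        spectra_path: str | Path,
        samples_per_plot: int,
        responses_path: str | Path | None = None,
        transpose: bool = False,
        drop_rows_matching: str | None = None,
    ) -> "SessionState":
        root = Path(root)
        root.mkdir(parents=True, exist_ok=True)
        dataset = load_spectra(
            spectra_path,
            samples_per_plot,
            transpose=transpose,
            drop_rows_matching=drop_rows_matching,
        )
        export_dataset(dataset, root / _ORIGINAL)
        export_dataset(dataset, root / _CURRENT)
        if responses_path is not None:
            responses = load_responses(responses_path)
            if responses.n_rows != dataset.n_scans:
                raise ConfigError(
                    f"{responses.n_rows} response rows but "
                    f"{dataset.n_scans} scans"
                )
            _write_responses(responses, root / _RESPONSES)
        (root / _META).write_text(
            json.dumps({"samples_per_scan": samples_per_plot}, indent=2)
        )
        state = cls(root=root, samples_per_scan=samples_per_plot, steps=[])
        state._write_log()
        return state

    @classmethod
    def load(cls, root: str | Path) -> "SessionState":
        root = Path(root)
        if not (root / _META).exists():
            raise LookupError(f"no session at {root}")
        meta = json.loads((root / _META).read_text())
        steps = json.loads((root / _LOG).read_text()) if (root / _LOG).exists() else []
        return cls(
            root=root, samples_per_scan=int(meta["samples_per_scan"]), steps=steps
        )

    # -- data access -----------------------------------------------------
    def original(self) -> SpectralDataset:
        return load_spectra(self.root / _ORIGINAL, self.samples_per_scan)

    def current(self) -> SpectralDataset:
        return load_spectra(self.root / _CURRENT, self.samples_per_scan)

    def dataset(self, source: str = "current") -> SpectralDataset:
        if source not in {"current", "original"}:
            raise ConfigError("source must be 'current' or 'original'")
        return self.current() if source == "current" else self.original()

    def responses(self) -> ResponseTable:
        path = self.root / _RESPONSES
        if not path.exists():
            raise LookupError("session has no response table")
        return load_responses(path)

    # -- step log --------------------------------------------------------
    def _write_log(self) -> None:
        (self.root / _LOG).write_text(json.dumps(self.steps, indent=2))

    def record_step(
        self,
        name: str,
        params: dict,
        dataset: SpectralDataset | None,
        source: str = "current",
        mutates: bool = True,
    ) -> None:
        """Append a step; persist the new current dataset if it mutates.

        ``source="original"`` restarts the pipeline: the log is reset to
        this single step before recording.
        """
        if mutates and source == "original":
            self.steps = []
        self.steps.append(
            {"step": name, "params": params, "source": source, "mutates": mutates}
        )
        if mutates:
            if dataset is None:
                raise ConfigError(f"mutating step {name!r} must supply a dataset")
            export_dataset(dataset, self.root / _CURRENT)
        self._write_log()

    # -- replay ----------------------------------------------------------
    def replay(self) -> SpectralDataset:
        """Re-apply the logged mutating steps to the original dataset."""
        dataset = self.original()
        for entry in self.steps:
            if not entry.get("mutates", False):
                continue
            dataset = _apply_step(dataset, entry["step"], entry["params"])
        return dataset

    def replay_matches_current(self) -> bool:
        """True iff replay reproduces the current export byte-identically."""
        replayed = self.replay()
        tmp = self.root / "replayed_spectra.csv"
        export_dataset(replayed, tmp)
        try:
            return tmp.read_bytes() == (self.root / _CURRENT).read_bytes()
        finally:
            tmp.unlink(missing_ok=True)


def _apply_step(
    dataset: SpectralDataset, step: str, params: dict
) -> SpectralDataset:
    if step == "noise":
        segments = [NoiseSegment(**seg) for seg in params["segments"]]
        result = apply_noise_filter(
            dataset, segments, drop_negatives=params.get("drop_negatives", False)
        )
        return result.dataset
    if step == "delete-samples":
        return delete_samples(
            dataset, params["plot"], [int(s) for s in params["samples"]]
        )
    if step == "remove-plots":
        return remove_plots(dataset, [int(p) for p in params["plots"]])
    raise ConfigError(f"unknown replayable step {step!r}")


def _write_responses(responses: ResponseTable, path: Path) -> None:
    frame = responses.codes.copy()
    for name in responses.variable_names:
        frame[name] = responses.variables[name]
    frame.to_csv(path, index=False, na_rep="")
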