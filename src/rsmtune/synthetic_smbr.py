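"""Synthetic submerged-membrane-bioreactor (SMBR) filtration data.

The generator emulates the structure of pilot-plant flux data: a suction pump
driven by random-magnitude voltage steps (0-3 V), a 120 s permeate / 30 s
relaxation duty cycle, transmembrane pressure (TMP, 0-270 mbar) that rises as
the membrane fouls, and permeate flux that tracks pump demand until the TMP
ceiling caps it. Fouling follows a resistance-in-series model: the fouling
resistance R_f grows in proportion to instantaneous flux during permeation
(dR_f/dt = a*J) and relaxes first-order during the aerated pause
(dR_f/dt = -b*R_f, with b modulated by the aeration rate). Flux obeys
J = TMP / (R_m + R_f) with R_m the clean-membrane resistance; the pump's
demanded flux sets TMP = J_demand * (R_m + R_f) up to the pressure ceiling,
beyond which flux falls below demand — the signature of fouling-limited
operation. Channels are sampled at 1 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "FiltrationDataset", "flux_from_volume", "generate"]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults give a 4000-sample, ~66-minute run."""

    n_samples: int = 4000
    seed: int = 0
    membrane_area: float = 0.35        # m^2
    clean_resistance: float = 1.0      # mbar per (L m^-2 h^-1)
    fouling_gain: float = 1e-4         # resistance growth per second per flux unit
    recovery_rate: float = 0.01        # 1/s first-order relaxation of R_f
    permeate_period: float = 120.0     # s
    relaxation_period: float = 30.0    # s
    step_dwell: tuple[float, float] = (120.0, 400.0)  # s, pump step duration range
    noise_sd: float = 1.0              # flux noise, L m^-2 h^-1
    pump_flux_gain: float = 25.0       # demanded flux per volt, L m^-2 h^-1 V^-1
    pump_range: tuple[float, float] = (0.0, 3.0)      # V
    tmp_max: float = 270.0             # mbar
    airflow_range: tuple[float, float] = (6.0, 8.0)   # SLPM
    use_airflow: bool = True           # modulate recovery by aeration intensity

    def __post_init__(self):
        for name in ("n_samples", "membrane_area", "clean_resistance",
                     "permeate_period", "relaxation_period", "pump_flux_gain", "tmp_max"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.fouling_gain < 0 or self.recovery_rate < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise_sd must be nonnegative")
        lo, hi = self.step_dwell
        if not 0 < lo <= hi:
            raise ValueError("step_dwell must be a positive (low, high) range")

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass
class FiltrationDataset:
    """Equal-length 1 Hz channels of one filtration run."""

    time: np.ndarray          # s
    pump_voltage: np.ndarray  # V
    tmp: np.ndarray           # mbar
    flux: np.ndarray          # L m^-2 h^-1
    airflow: np.ndarray       # SLPM
    config: SimConfig | None = None

    def __len__(self) -> int:
        return len(self.time)

    @property
    def inputs(self) -> np.ndarray:
        """The soft-sensor input matrix: pump voltage and TMP, one row per sample."""
        return np.column_stack([self.pump_voltage, self.tmp])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "pump_v": self.pump_voltage,
                "tmp_mbar": self.tmp,
                "airflow_slpm": self.airflow,
                "flux_lmh": self.flux,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "FiltrationDataset":
        df = pd.read_csv(path)
        return FiltrationDataset(
            time=df["time_s"].to_numpy(dtype=float),
            pump_voltage=df["pump_v"].to_numpy(dtype=float),
            tmp=df["tmp_mbar"].to_numpy(dtype=float),
            flux=df["flux_lmh"].to_numpy(dtype=float),
            airflow=df["airflow_slpm"].to_numpy(dtype=float),
        )


def flux_from_volume(v: float, area: float, t: float) -> float:
    """Permeate flux J = v / (A * t) in L m^-2 h^-1 from volume v (L),
    membrane area A (m^2) and duration t (h)."""
    if not area > 0:
        raise ValueError("membrane area must be positive")
    if not t > 0:
        raise ValueError("duration must be positive")
    return v / (area * t)


def _step_series(rng: np.random.Generator, n: int, dwell: tuple[float, float],
                 lo: float, hi: float) -> np.ndarray:
    """Piecewise-constant series of random-magnitude steps with random dwell."""
    out = np.empty(n)
    i = 0
    while i < n:
        width = int(rng.uniform(*dwell))
        out[i : i + width] = rng.uniform(lo, hi)
        i += width
    return out


def generate(config: SimConfig = SimConfig()) -> FiltrationDataset:
    """Simulate one filtration run; deterministic per ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    time = np.arange(n, dtype=float)

    lo_p, hi_p = config.pump_range
    # steps avoid the bottom sixth of the range so permeation always filters
    pump = _step_series(rng, n, config.step_dwell, lo_p + (hi_p - lo_p) / 6, hi_p)
    airflow = _step_series(rng, n, (200.0, 600.0), *config.airflow_range)

    cycle = config.permeate_period + config.relaxation_period
    permeating = (time % cycle) < config.permeate_period

    rm = config.clean_resistance
    rf = 0.0
    tmp = np.zeros(n)
    flux = np.zeros(n)
    noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else np.zeros(n)
    for i in range(n):
        if permeating[i]:
            demand = config.pump_flux_gain * pump[i]
            tmp_i = min(demand * (rm + rf), config.tmp_max)
            j_i = tmp_i / (rm + rf)
            rf += config.fouling_gain * j_i
            tmp[i] = tmp_i
            flux[i] = max(j_i + noise[i], 0.0)
        else:
            b = config.recovery_rate
            if config.use_airflow:
                b *= airflow[i] / np.mean(config.airflow_range)
            rf *= max(1.0 - b, 0.0)
            tmp[i] = 0.0
            flux[i] = 0.0

    np.clip(pump, lo_p, hi_p, out=pump)
    np.clip(tmp, 0.0, config.tmp_max, out=tmp)
    return FiltrationDataset(
        time=time, pump_voltage=pump, tmp=tmp, flux=flux, airflow=airflow, config=config
    )
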