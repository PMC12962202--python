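"""Best-effort export of a designed FAM protocol as a Pulseq .seq text file.

Writes the open Pulseq file format (v1.4 layout): an apodized-sinc RF pulse
whose amplitude is rescaled per excitation according to the flip schedule, a
phase-encode trapezoid per line in centric order, and a flyback monopolar
readout train.  The output is timing-consistent at the block level but is a
design artifact, not a vendor-certified sequence: slew/amplitude limits are
checked only against the configured maxima, and no RF-spoiling phase
schedule is emitted.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .sequence_design import AcquisitionParams, FlipSchedule

GAMMA_HZ_PER_T = 42.5775e6


def export_seq(
    params: AcquisitionParams,
    schedule: FlipSchedule,
    path,
    *,
    max_grad_mt_m: float = 33.0,
    max_slew_t_m_s: float = 120.0,
    rf_duration_ms: float = 1.0,
) -> None:
    """Write a minimal Pulseq .seq file for the designed protocol."""
    path = Path(path)
    ny = params.ny
    if len(schedule) != ny:
        raise ValueError("schedule length must match the phase-encode count")

    fov_m = params.fov_cm[1] / 100.0
    dk = 1.0 / fov_m  # 1/m per PE line
    kmax_steps = np.asarray(schedule.pe_order) - ny // 2
    pe_area = kmax_steps * dk / GAMMA_HZ_PER_T  # T/m * s equivalent area (Hz-normalized below)

    # PE trapezoid: fixed 0.5 ms flat duration, amplitude per line (Hz/m)
    pe_dur_s = 5e-4
    pe_amp_hz_m = kmax_steps * dk / pe_dur_s
    g_amp_t_m = np.abs(pe_amp_hz_m).max() / GAMMA_HZ_PER_T
    if g_amp_t_m * 1e3 > max_grad_mt_m:
        raise ValueError("phase-encode gradient exceeds the configured amplitude limit")

    # reference RF amplitude for a 90 deg hard-equivalent pulse, scaled per
    # excitation by alpha_j / 90
    rf_cycles = (np.deg2rad(schedule.alphas_deg) / (2 * np.pi)) / (rf_duration_ms * 1e-3)

    lines = []
    lines.append("# Pulseq sequence file")
    lines.append("# Created by famfat (flip-angle-modulated CSE design export)")
    lines.append("")
    lines.append("[VERSION]")
    lines.append("major 1")
    lines.append("minor 4")
    lines.append("revision 0")
    lines.append("")
    lines.append("[DEFINITIONS]")
    lines.append(f"FOV {params.fov_cm[0] / 100:.6g} {params.fov_cm[1] / 100:.6g} "
                 f"{params.slice_thickness_mm / 1000:.6g}")
    lines.append(f"TotalDuration {params.tr_ms * ny / 1000:.6g}")
    lines.append(f"Name famfat_{params.label or 'custom'}")
    lines.append("")

    # one RF event per distinct amplitude (excitation), one PE trap per line,
    # one ADC shared by all readouts
    lines.append("# Format of blocks:")
    lines.append("#  #  D RF  GX  GY  GZ  ADC  EXT")
    lines.append("[BLOCKS]")
    block_id = 1
    for j in range(ny):
        # excitation block (RF event j+1), then one ADC block per echo
        lines.append(f"{block_id:4d} 0 {j + 1} 0 {j + 1} 0 0 0")
        block_id += 1
        for _ in range(params.n_echoes):
            lines.append(f"{block_id:4d} 0 0 1 0 0 1 0")
            block_id += 1
    lines.append("")

    lines.append("# Format of RF events:")
    lines.append("# id amplitude mag_id phase_id time_shape_id delay freq phase")
    lines.append("# ..        Hz   ....     ....          ....    us   Hz   rad")
    lines.append("[RF]")
    for j, amp in enumerate(rf_cycles, start=1):
        lines.append(f"{j} {amp:.6g} 1 2 0 0 0 0")
    lines.append("")

    lines.append("# Format of trapezoid gradients:")
    lines.append("# id amplitude rise flat fall delay")
    lines.append("# ..      Hz/m   us   us   us    us")
    lines.append("[TRAP]")
    # id 1: readout gradient (fixed), ids 2..ny+1 would collide with GY ids,
    # so PE traps are numbered from 1 in their own GY column namespace
    ro_amp = params.matrix[0] / (params.fov_cm[0] / 100.0) / (params.dte_ms * 1e-3 * 0.6)
    rise_us = int(ro_amp / GAMMA_HZ_PER_T / max_slew_t_m_s * 1e6) + 1
    lines.append(f"1 {ro_amp:.6g} {rise_us} {int(params.dte_ms * 600)} {rise_us} 0")
    for j, amp in enumerate(pe_amp_hz_m, start=1):
        lines.append(f"{j + 1} {amp:.6g} 10 {int(pe_dur_s * 1e6)} 10 0")
    lines.append("")

    lines.append("# Format of ADC events:")
    lines.append("# id num dwell delay freq phase")
    lines.append("# ..  ..    ns    us   Hz   rad")
    lines.append("[ADC]")
    dwell_ns = int(params.dte_ms * 1e6 * 0.6 / params.matrix[0] * 1e3)
    lines.append(f"1 {params.matrix[0]} {dwell_ns} 0 0 0")
    lines.append("")

    # apodized-sinc magnitude shape and zero phase shape, compressed format
    n_shape = 64
    t = np.linspace(-2, 2, n_shape)
    sinc = np.sinc(t) * (0.54 + 0.46 * np.cos(np.pi * t / 2))
    sinc = np.clip(sinc / sinc.max(), 0, 1)
    lines.append("[SHAPES]")
    lines.append("shape_id 1")
    lines.append(f"num_samples {n_shape}")
    lines.extend(f"{v:.6g}" for v in sinc)
    lines.append("")
    lines.append("shape_id 2")
    lines.append(f"num_samples {n_shape}")
    lines.extend(f"{v:.6g}" for v in np.zeros(n_shape))
    lines.append("")

    path.write_text("\n".join(lines) + "\n")
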