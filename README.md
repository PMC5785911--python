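# voxmc

Voxelized Monte Carlo photon transport for 3-D heterogeneous turbid media,
with the load-balancing machinery needed to split a simulation across
heterogeneous compute devices.

The transport kernel marches photon packets voxel by voxel: each sub-step
advances by the minimum of the remaining scattering path and the exact
distance to the nearest voxel face, deposits `w·(1 − exp(−μa·d))` of packet
weight in the current voxel, samples scattering directions from the
Henyey–Greenstein phase function, evaluates unpolarized Fresnel
reflection/refraction at refractive-index mismatches, and terminates
low-weight packets with Russian roulette. Output is the 3-D fluence volume
(absorbed energy normalized by `μa · voxel volume · launched weight`). The
hot loop is JIT-compiled with numba; results are bit-reproducible for a
fixed seed and worker count.

## Modules

| module | contents |
| --- | --- |
| `voxmc.scene` | voxel grids, optical property tables, pencil/isotropic sources, the built-in `B1`/`B2`/`B2a` benchmark scenes |
| `voxmc.rng` | per-worker independent xoshiro256++ streams keyed by `(seed, stream_id)` |
| `voxmc.transport` | the photon loop (launch / hop / drop / spin / Fresnel / roulette) and `run()` |
| `voxmc.accumulate` | deposit volumes, atomic/nonatomic merge contracts, fluence normalization |
| `voxmc.scheduler` | thread-count heuristic, dynamic workgroup photon pool, device calibration `T = a·n + T0`, partition strategies S1 (cores), S2 (1/a), S3 (minimax makespan) |
| `voxmc.validate` | diffusion-theory Green's function, angle-form Fresnel oracle, HG moments, conservation audits |
| `voxmc.cli` / `voxmc.io` | `voxmc` command line, JSON configs, raw uint8 volumes and float32 fluence files (x-fastest order) |

## Benchmarks

All three built-in scenes are a 60×60×60 mm³ cube (μa = 0.005/mm,
μs = 1.0/mm, g = 0.01, n = 1.37) with a pencil beam entering at
(30, 30, 0) mm along +z. `B1` terminates photons at the cube surface;
`B2`/`B2a` add a 15 mm-radius spherical inclusion (μa = 0.002/mm,
μs = 5.0/mm, g = 0.9, n = 1.0) at the center and apply Fresnel physics at
every index mismatch. `B2` and `B2a` differ only in the accumulation mode
they request (nonatomic vs atomic).

## CLI

```sh
voxmc benchmark B1 --nphoton 100000 --seed 1 --output out/b1
voxmc run --config config.json
voxmc validate --seed 1 --out validation.json
voxmc calibrate --pilot 1000000:1053 --pilot 5000000:5253
voxmc partition --total 100000000 --devices pool.json --strategy S3
```

`benchmark`/`run` write `<prefix>.mc2` (flat float32 fluence, x-fastest
order) plus `<prefix>.json` (dimensions, pitch, seed actually used,
normalization, conservation audit). `--seed auto` draws a seed from system
entropy and records it in the sidecar. Device pools are JSON lists of
`{"name", "cores", "max_threads_per_cu", "num_cus", "a_ms_per_photon",
"T0_ms"}`.

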