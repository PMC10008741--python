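"""Streaming-acquisition arithmetic for a four-system matrix-array scan.

A 32×32 matrix probe driven by four synchronized 256-channel systems
acquires 5-angle plane-wave volumes at 500 volumes/s in 100-volume blocks.
This prints the block timing and the storage the stream generates.
"""

from ulm3d.core import AcquisitionPlan, plan_acquisition, truncate, wavelength_um

lam = wavelength_um(7.81e6)
print(f"wavelength at 7.81 MHz:      {lam:.2f} um")
print(f"beamforming voxel (lambda/2): {lam / 2:.1f} um")
print(f"rendering voxel (lambda/20):  {truncate(lam / 20, 1):.1f} um (truncated display)")

plan = AcquisitionPlan()  # 1024 samples, 5 TX, 100 volumes/block, 500 vps, 100k volumes
summary = plan_acquisition(plan, block_bytes_per_system=245_000_000)
print(f"\nblock duration:   {summary['block_duration_s'] * 1e3:.0f} ms")
print(f"total scan:       {summary['total_duration_s']:.0f} s "
      f"({plan.total_volumes:,} volumes)")
print(f"block storage:    {summary['block_bytes_total'] / 1e6:.0f} MB across "
      f"{plan.n_systems} systems")
print(f"dataset storage:  {summary['dataset_bytes_total'] / 1e9:.0f} GB "
      f"({summary['n_blocks']:.0f} blocks)")
# The per-system 245 MB block size is a measured figure (vendor buffers pad
# the raw 1024×5×100×256×2-byte product), so it is passed in, not derived.
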