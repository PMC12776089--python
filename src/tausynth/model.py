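"""The covariate-modulated attention U-Net for MRI-to-tau-PET synthesis.

Architecture, in three stages mirroring the pipeline:

1. tabular estimates (regional tau means/SDs, MetaTempTau, amyloid status,
   MMSE) arrive from :mod:`tausynth.tabular`;
2. an attention U-Net encodes the MRI and decodes it with conditionally
   parameterized upsampling convolutions routed by the conditioning vector
   (age, sex, education, predicted MMSE, predicted MetaTempTau) to an
   initial prediction Z;
3. a dynamic prompt F is selected per subject from a bank indexed by
   predicted amyloid status, modulated by the regional tau tensors, and
   fused with Z into the final non-negative SUVR volume:

       F_mod = F + ConvBlocks(F_c (+) S_hat (+) Gamma_hat)
       P_hat = ReLU(Conv(Z (+) ConvBlocks(F_mod (+) Z)))

   where (+) is channel concatenation, Gamma_hat carries the predicted
   regional tau mean at each ROI voxel (zero on background) and S_hat the
   corresponding SD. The modulation ConvBlocks ends in a zero-initialized
   conv so F_mod == F exactly at initialization.

The ablated variant (``ablated=True``) drops conditioning and modulation,
reducing the model to a plain attention U-Net whose output is independent
of covariates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .atlas import Atlas
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import (AttentionGate, CondConv3d, Conv3d, ConvBlocks,
                        ConvStage, DoubleConv, Module)
from .tabular import AuxiliaryEstimates

CONDITIONING_FIELDS = ("age", "sex", "education", "mmse_hat", "meta_temp_hat")


@dataclass
class NetworkConfig:
    grid: tuple[int, int, int]
    encoder_channels: tuple = (16, 32, 64, 128)
    conditioning_dim: int = 5
    prompt_bank_size: int = 2
    prompt_channels: int = 4
    head_channels: int = 8
    dropout_rate: float = 0.1
    negative_slope: float = 0.25
    cond_experts: int = 4
    ablated: bool = False
    modulation_includes_gamma: bool = True

    def __post_init__(self):
        self.grid = tuple(int(g) for g in self.grid)
        self.encoder_channels = tuple(int(c) for c in self.encoder_channels)
        levels = len(self.encoder_channels)
        div = 2 ** (levels - 1)
        if any(g % div for g in self.grid):
            raise ValueError(f"grid {self.grid} not divisible by 2^(levels-1)={div}")
        if self.prompt_bank_size < 1:
            raise ValueError("prompt_bank_size must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class RegionalPromptInputs:
    """Voxel tensors of predicted regional tau mean / SD plus the prompt index."""

    gamma_hat: np.ndarray   # (N, 1, D, H, W)
    s_hat: np.ndarray       # (N, 1, D, H, W)
    covariate_index: np.ndarray  # (N,) ints in [0, prompt_bank_size)


def build_regional_tensors(estimates: list[AuxiliaryEstimates], atlas: Atlas) -> RegionalPromptInputs:
    """Scatter per-ROI estimates into voxel maps; zeros exactly on background."""
    lab = atlas.label_volume
    n = len(estimates)
    gamma = np.zeros((n, 1) + atlas.grid)
    shat = np.zeros((n, 1) + atlas.grid)
    idx = np.zeros(n, dtype=int)
    for i, e in enumerate(estimates):
        missing = [r for r in atlas.roi_ids if r not in e.tau_hat]
        if missing:
            raise ValueError(f"estimates missing ROIs {missing}")
        lut_m = np.zeros(max(atlas.roi_ids) + 1)
        lut_s = np.zeros(max(atlas.roi_ids) + 1)
        for rid in atlas.roi_ids:
            lut_m[rid] = e.tau_hat[rid]
            lut_s[rid] = e.sigma_hat[rid]
        gamma[i, 0] = lut_m[lab]
        shat[i, 0] = lut_s[lab]
        idx[i] = e.abeta_status
    return RegionalPromptInputs(gamma, shat, idx)


def preprocess_mri(volume: np.ndarray, grid: tuple[int, int, int]) -> np.ndarray:
    """Bring a positive-intensity volume onto the model grid.

    Nearest-neighbour resampling with a single isotropic factor (the smallest
    grid/shape ratio), symmetric edge padding on any short axis (the axial
    axis in the canonical case), and central cropping. Deterministic; output
    voxel values are a subset of the input values.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.size == 0 or volume.ndim != 3:
        raise ValueError("expected a non-empty 3D volume")
    if volume.max() <= 0:
        raise ValueError("expected a positive-intensity volume")
    grid = tuple(int(g) for g in grid)
    f = min(g / s for g, s in zip(grid, volume.shape))
    new_shape = [min(g, int(round(s * f))) for g, s in zip(grid, volume.shape)]
    idx = [np.minimum((np.arange(m) + 0.5) * s / m, s - 1).astype(int)
           for m, s in zip(new_shape, volume.shape)]
    out = volume[np.ix_(*idx)]
    pads, crops = [], []
    for g, m in zip(grid, out.shape):
        if m < g:
            lo = (g - m) // 2
            pads.append((lo, g - m - lo))
            crops.append(slice(None))
        else:
            pads.append((0, 0))
            lo = (m - g) // 2
            crops.append(slice(lo, lo + g))
    out = np.pad(out, pads, mode="edge")[tuple(crops)]
    return out


class SynthesisModel(Module):
    """Encoder -> attention-gated skips -> conditional decoder -> prompt modulation."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.drop_rng = np.random.default_rng(rng.integers(2 ** 31))
        ch = config.encoder_channels
        dr = config.dropout_rate

        self.enc = [DoubleConv(rng, 1 if i == 0 else ch[i - 1], ch[i], dr, self.drop_rng)
                    for i in range(len(ch))]
        self.up, self.gates, self.dec = [], [], []
        for lv in range(len(ch) - 2, -1, -1):
            if config.ablated:
                self.up.append(Conv3d(rng, ch[lv + 1], ch[lv]))
            else:
                self.up.append(CondConv3d(rng, ch[lv + 1], ch[lv], config.conditioning_dim,
                                          n_experts=config.cond_experts))
            self.gates.append(AttentionGate(rng, ch[lv], ch[lv]))
            self.dec.append(DoubleConv(rng, 2 * ch[lv], ch[lv], dr, self.drop_rng))
        self.z_conv = Conv3d(rng, ch[0], 1)

        pc, hc = config.prompt_channels, config.head_channels
        if not config.ablated:
            self.prompt = Tensor(rng.normal(0, 0.1, size=(1, pc) + config.grid), requires_grad=True)
            self.prompt_bank = Tensor(rng.normal(0, 0.1, size=(config.prompt_bank_size, pc) + config.grid),
                                      requires_grad=True)
            mod_in = pc + (2 if config.modulation_includes_gamma else 1)
            self.mod_blocks = ConvBlocks(rng, mod_in, pc, dr, self.drop_rng, zero_init_last=True)
            head_in = pc + 1 + (0 if config.modulation_includes_gamma else 1)
            self.head_blocks = ConvBlocks(rng, head_in, hc, dr, self.drop_rng)
            self.head_stage = ConvStage(rng, hc + 1, hc, dr, self.drop_rng)
        else:
            self.head_stage = ConvStage(rng, 1, hc, dr, self.drop_rng)
        self.proj = Conv3d(rng, hc, 1, k=1)

        # conditioning standardization (training-set statistics)
        self.cond_mean = np.zeros(config.conditioning_dim)
        self.cond_sd = np.ones(config.conditioning_dim)

    # -- conditioning ---------------------------------------------------
    def set_conditioning_stats(self, mean: np.ndarray, sd: np.ndarray):
        self.cond_mean = np.asarray(mean, dtype=float)
        sd = np.asarray(sd, dtype=float)
        self.cond_sd = np.where(sd > 0, sd, 1.0)

    def standardize_conditioning(self, cond: np.ndarray) -> np.ndarray:
        cond = np.atleast_2d(np.asarray(cond, dtype=float))
        if cond.shape[1] != self.config.conditioning_dim:
            raise ValueError(f"conditioning dim {cond.shape[1]} != {self.config.conditioning_dim}")
        return (cond - self.cond_mean) / self.cond_sd

    # -- stages ---------------------------------------------------------
    def backbone(self, mri: Tensor, cond: np.ndarray | None) -> Tensor:
        """Encoder / attention-gated conditional decoder; returns Z (N,1,grid)."""
        cond_t = None if (cond is None or self.config.ablated) else Tensor(cond)
        skips = []
        x = mri
        for i, blk in enumerate(self.enc):
            x = blk(x)
            if i < len(self.enc) - 1:
                skips.append(x)
                x = ad.avg_pool3d_2(x)
        g = x
        for j, lv in enumerate(range(len(self.enc) - 2, -1, -1)):
            up = ad.upsample3d_2(g)
            up = self.up[j](up, cond_t) if not self.config.ablated else self.up[j](up)
            sk = self.gates[j](skips[lv], up)
            g = self.dec[j](ad.concat([up, sk], axis=1))
        return self.z_conv(g)

    def modulate_prompt(self, inputs: RegionalPromptInputs) -> Tensor:
        """F_mod = F + ConvBlocks(F_c (+) S_hat [(+) Gamma_hat])."""
        if self.config.ablated:
            raise RuntimeError("ablated model has no prompt path")
        idx = np.asarray(inputs.covariate_index, dtype=int)
        if (idx < 0).any() or (idx >= self.config.prompt_bank_size).any():
            raise ValueError(f"covariate_index out of range [0, {self.config.prompt_bank_size})")
        fc = ad.take0(self.prompt_bank, idx)
        parts = [fc, Tensor(inputs.s_hat)]
        if self.config.modulation_includes_gamma:
            parts.append(Tensor(inputs.gamma_hat))
        return self.prompt + self.mod_blocks(ad.concat(parts, axis=1))

    def final_prediction(self, z: Tensor, f_mod: Tensor,
                         gamma: np.ndarray | None = None) -> Tensor:
        """P_hat = ReLU(Conv(Z (+) ConvBlocks(F_mod (+) Z)))."""
        parts = [f_mod, z]
        if not self.config.modulation_includes_gamma:
            if gamma is None:
                raise ValueError("alternative modulation reading requires gamma at the head")
            parts.insert(1, Tensor(gamma))
        t = self.head_blocks(ad.concat(parts, axis=1))
        u = self.head_stage(ad.concat([z, t], axis=1))
        return ad.relu(self.proj(u))

    def forward(self, mri: np.ndarray, conditioning: np.ndarray | None = None,
                prompts: RegionalPromptInputs | None = None) -> Tensor:
        mri_t = Tensor(self._shape_input(mri))
        if self.config.ablated:
            z = self.backbone(mri_t, None)
            return ad.relu(self.proj(self.head_stage(z)))
        if conditioning is None or prompts is None:
            raise ValueError("full model requires conditioning and regional prompt inputs")
        cond = self.standardize_conditioning(conditioning)
        z = self.backbone(mri_t, cond)
        f_mod = self.modulate_prompt(prompts)
        return self.final_prediction(z, f_mod, gamma=prompts.gamma_hat)

    def predict(self, mri, conditioning=None, prompts=None) -> np.ndarray:
        """Evaluation-mode forward returning (N, D, H, W) numpy volumes."""
        was_training = self.training
        self.eval()
        try:
            out = self.forward(mri, conditioning, prompts).data[:, 0]
        finally:
            if was_training:
                self.train()
        return out

    def _shape_input(self, mri: np.ndarray) -> np.ndarray:
        mri = np.asarray(mri, dtype=float)
        if mri.ndim == 3:
            mri = mri[None, None]
        elif mri.ndim == 4:
            mri = mri[:, None]
        if mri.shape[2:] != self.config.grid:
            raise ValueError(f"input spatial shape {mri.shape[2:]} != grid {self.config.grid}")
        return mri

    # -- checkpointing --------------------------------------------------
    def save(self, path: str | Path):
        path = Path(path)
        cfg = asdict(self.config)
        np.savez_compressed(
            path, __format__=np.array(["tausynth-checkpoint-1"]),
            __config__=np.array([json.dumps(cfg)]),
            cond_mean=self.cond_mean, cond_sd=self.cond_sd,
            **{f"p{i}": a for i, a in enumerate(self.state_arrays())})

    @classmethod
    def load(cls, path: str | Path, seed: int = 0) -> "SynthesisModel":
        with np.load(path, allow_pickle=False) as z:
            if "__format__" not in z or str(z["__format__"][0]) != "tausynth-checkpoint-1":
                raise ValueError(f"{path}: not a recognized checkpoint")
            cfg = json.loads(str(z["__config__"][0]))
            model = cls(NetworkConfig(**cfg), seed=seed)
            n = len(model.parameters())
            model.load_state_arrays([z[f"p{i}"] for i in range(n)])
            model.set_conditioning_stats(z["cond_mean"], z["cond_sd"])
        return model


def conditioning_matrix(feature_df, estimates: list[AuxiliaryEstimates]) -> np.ndarray:
    """Assemble raw conditioning rows: age, sex (as +-1), education, MMSE-hat,
    MetaTempTau-hat. ``feature_df`` should already be imputed."""
    age = feature_df["age"].to_numpy(float)
    sex = np.where(feature_df["sex"].to_numpy(float) > 0.5, 1.0, -1.0)
    edu = feature_df["education"].to_numpy(float)
    mm = np.array([e.mmse_hat for e in estimates])
    mt = np.array([e.meta_temp_hat for e in estimates])
    return np.column_stack([age, sex, edu, mm, mt])
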