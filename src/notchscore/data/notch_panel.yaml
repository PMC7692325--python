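# Curated panel of 18 direct NOTCH target genes with a best-effort
# Affymetrix HG-U133Plus2.0 probeset mapping.  The probeset lists are an
# editable stand-in assembled from platform annotation; regenerate from
# hgu133plus2.db + manual curation (intronic / opposite-strand / wrong-
# chromosome probesets excluded) before use on real arrays.
pathway_name: NOTCH
version: "0.1-standin"
genes:
  - {symbol: CD44, direction: 1}
  - {symbol: DTX1, direction: 1}
  - {symbol: EPHB3, direction: 1}
  - {symbol: HES1, direction: 1}
  - {symbol: HES4, direction: 1}
  - {symbol: HES5, direction: 1}
  - {symbol: HES7, direction: 1}
  - {symbol: HEY1, direction: 1}
  - {symbol: HEY2, direction: 1}
  - {symbol: HEYL, direction: 1}
  - {symbol: MYC, direction: 1}
  - {symbol: NFKB2, direction: 1}
  - {symbol: NOX1, direction: 1}
  - {symbol: NRARP, direction: 1}
  - {symbol: PBX1, direction: 1}
  - {symbol: PIN1, direction: 1}
  - {symbol: PLXND1, direction: 1}
  - {symbol: SOX9, direction: 1}
probesets:
  - {id: 204489_s_at, gene: CD44, included: true}
  - {id: 204490_s_at, gene: CD44, included: true}
  - {id: 212063_at, gene: CD44, included: true}
  - {id: 217523_at, gene: CD44, included: true}
  - {id: 227336_at, gene: DTX1, included: true}
  - {id: 204600_at, gene: EPHB3, included: true}
  - {id: 1438_at, gene: EPHB3, included: true}
  - {id: 203395_s_at, gene: HES1, included: true}
  - {id: 203396_at, gene: HES1, included: true}
  - {id: 226446_at, gene: HES4, included: true}
  - {id: 239230_at, gene: HES5, included: true}
  - {id: 1552622_s_at, gene: HES7, included: true}
  - {id: 218839_at, gene: HEY1, included: true}
  - {id: 44783_s_at, gene: HEY1, included: true}
  - {id: 219743_at, gene: HEY2, included: true}
  - {id: 220662_s_at, gene: HEYL, included: true}
  - {id: 202431_s_at, gene: MYC, included: true}
  - {id: 207535_s_at, gene: NFKB2, included: true}
  - {id: 209636_at, gene: NFKB2, included: true}
  - {id: 207217_s_at, gene: NOX1, included: true}
  - {id: 233413_at, gene: NRARP, included: true}
  - {id: 205253_at, gene: PBX1, included: true}
  - {id: 212148_at, gene: PBX1, included: true}
  - {id: 202927_at, gene: PIN1, included: true}
  - {id: 212235_at, gene: PLXND1, included: true}
  - {id: 202935_s_at, gene: SOX9, included: true}
  - {id: 202936_s_at, gene: SOX9, included: true}
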