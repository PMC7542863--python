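# Reference global Moran's I values computed with ape::Moran.I.
#
# Driven by scripts/make_r_reference.py, which writes each case as a pair of
# CSVs (values + dense weight matrix) under scratch/r_reference/ and freezes
# the results into tests/data/moran_reference.json.  ape reports Moran's I
# without the n/S0 scaling convention choice ambiguity: it uses
# I = (n/S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 for the supplied matrix.

suppressMessages(library(ape))

args <- commandArgs(trailingOnly = TRUE)
indir <- args[1]

cases <- list.files(indir, pattern = "_x\\.csv$")
out <- character(0)
for (f in cases) {
  name <- sub("_x\\.csv$", "", f)
  x <- as.numeric(read.csv(file.path(indir, f), header = FALSE)[[1]])
  w <- as.matrix(read.csv(file.path(indir, paste0(name, "_w.csv")), header = FALSE))
  res <- Moran.I(x, w, scaled = FALSE)
  out <- c(out, sprintf('"%s": %.15g', name, res$observed))
}
cat("{", paste(out, collapse = ", "), "}\n")
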