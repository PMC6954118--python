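#!/usr/bin/env Rscript
# Independent attractor cross-check with the BoolNet CRAN package.
#
# Loads a .boolnet model file and its companion initial-values CSV (as
# exported by `bbmnet compile`), runs the synchronous update scheme from
# that initial state until a state recurs, and writes the attractor as a
# CSV in the same layout as the native engine's attractor export
# (columns: symbol,value; one file column block per attractor state).
#
# Usage:
#   Rscript scripts/boolnet_crosscheck.R model.boolnet model_initial_vals.csv out.csv
#
# Requires the BoolNet package (install.packages("BoolNet")); if it is
# not installed the script reports the failure in the output file
# instead of crashing, so callers can treat the check as unavailable.

args <- commandArgs(trailingOnly = TRUE)
if (length(args) != 3) {
  stop("usage: boolnet_crosscheck.R <model.boolnet> <initial_vals.csv> <out.csv>")
}
model_file <- args[1]
init_file <- args[2]
out_file <- args[3]

if (!requireNamespace("BoolNet", quietly = TRUE)) {
  writeLines("error,BoolNet package not installed", out_file)
  quit(status = 0)
}
suppressMessages(library(BoolNet))

net <- loadNetwork(model_file)
init_tab <- read.csv(init_file, stringsAsFactors = FALSE)
state <- as.integer(init_tab$value[match(net$genes, init_tab$symbol)])
if (any(is.na(state))) {
  writeLines("error,initial values do not cover all targets", out_file)
  quit(status = 0)
}

# Synchronous iteration with exact repeat detection.
seen <- new.env(hash = TRUE)
trajectory <- list()
key <- function(v) paste(v, collapse = "")
v <- state
while (is.null(seen[[key(v)]])) {
  seen[[key(v)]] <- length(trajectory) + 1L
  trajectory[[length(trajectory) + 1L]] <- v
  v <- stateTransition(net, v, type = "synchronous")
}
start <- seen[[key(v)]]
attractor <- trajectory[start:length(trajectory)]

out <- data.frame(symbol = net$genes)
for (i in seq_along(attractor)) {
  out[[paste0("state", i)]] <- attractor[[i]]
}
write.csv(out, out_file, row.names = FALSE, quote = FALSE)
cat(sprintf("attractor period %d written to %s\n", length(attractor), out_file))
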