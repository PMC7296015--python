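# Batch glmmTMB fitting bridge.
#
# Usage: Rscript fit_glmmtmb.R <job.json> <out.json>
#
# job.json:
#   data_csv : path to the model data (one row per record)
#   models   : list of {id, family ("zibinomial" | "gaussian"), fixed (RHS string),
#               subset (optional: fit only rows whose `replicate` column equals it)}
#   random   : random-effects RHS appended to every model,
#              e.g. "(1|year) + (1|group_id/animal_id)"
#   factors  : column names to coerce to factor
#
# For family "zibinomial" the response is cbind(ete_count, active_nights -
# ete_count) with an intercept-only structural-zero component (ziformula =
# ~1); for "gaussian" the response is the column y. Writes one JSON record
# per model: fixed-effect table, zero-inflation table, logLik and its df,
# nobs, the conditional-model vcov, and convergence diagnostics.

suppressMessages({
  library(glmmTMB)
  library(jsonlite)
})

args <- commandArgs(trailingOnly = TRUE)
job <- fromJSON(args[[1]], simplifyDataFrame = FALSE)
dat <- read.csv(job$data_csv, stringsAsFactors = FALSE)
for (f in job$factors) dat[[f]] <- factor(dat[[f]])

coef_table <- function(cm) {
  list(
    term = rownames(cm),
    estimate = unname(cm[, 1]),
    std_error = unname(cm[, 2]),
    z = unname(cm[, 3]),
    p_value = unname(cm[, 4])
  )
}

fit_one <- function(m) {
  dat <- if (!is.null(m$subset)) dat[dat$replicate == m$subset, , drop = FALSE] else dat
  rhs <- paste(m$fixed, job$random, sep = " + ")
  if (identical(m$family, "zibinomial")) {
    form <- as.formula(paste("cbind(ete_count, active_nights - ete_count) ~", rhs))
    fit <- glmmTMB(form, ziformula = ~1, family = binomial, data = dat)
  } else if (identical(m$family, "gaussian")) {
    form <- as.formula(paste("y ~", rhs))
    fit <- glmmTMB(form, family = gaussian, data = dat)
  } else {
    stop(paste("unknown family", m$family))
  }
  s <- summary(fit)
  ll <- logLik(fit)
  vc <- tryCatch(vcov(fit)$cond, error = function(e) NULL)
  conv <- isTRUE(fit$fit$convergence == 0)
  pdh <- isTRUE(fit$sdr$pdHess)
  out <- list(
    id = m$id,
    converged = conv && pdh,
    optimizer_converged = conv,
    pd_hess = pdh,
    loglik = as.numeric(ll),
    df = attr(ll, "df"),
    nobs = nobs(fit),
    aic = AIC(fit),
    coefficients = coef_table(s$coefficients$cond)
  )
  if (!is.null(s$coefficients$zi)) {
    out$zi_coefficients <- coef_table(s$coefficients$zi)
  }
  if (!is.null(vc)) {
    out$vcov_terms <- rownames(vc)
    out$vcov <- unname(as.matrix(vc))
  }
  out
}

results <- lapply(job$models, function(m) {
  tryCatch(fit_one(m), error = function(e) list(id = m$id, converged = FALSE, error = conditionMessage(e)))
})

writeLines(toJSON(results, digits = NA, auto_unbox = TRUE, na = "null"), args[[2]])
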