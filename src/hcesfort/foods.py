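"""Food-list metadata for a 60-item household consumption module.

The food list mirrors the structure of the 7-day food module used by
national panel surveys in East Africa: sixty predefined items covering
cereals and flours, roots, pulses, vegetables and fruit (some of them
concatenated multi-food items), animal-source foods, fats, and drinks.
Quantities may be reported in kilograms, grams, litres, millilitres or
pieces; each item therefore carries a refuse fraction, a density where it
is a liquid, and a portion mass where it is counted in pieces.

Three items are fortification *vehicles* (cooking oil, wheat flour, maize
flour) and three processed products (bread; buns, cakes and biscuits;
sweets) embed wheat flour and oil via recipes. Macaroni/spaghetti is
deliberately not a recipe product: the origin of the flour it contains is
unknown, so it contributes nothing to wheat-flour equivalents.

Nutrient values are per 100 g edible portion and are synthetic but
plausible entries modelled on regional food composition tables; each row
carries a provenance label mimicking the FCT-priority protocol
(Kenya > West Africa > US > Tanzania).
"""

from __future__ import annotations

from dataclasses import dataclass, field

NUTRIENTS = [
    "energy_kcal",
    "iron_mg",
    "zinc_mg",
    "vita_rae_ug",
    "retinol_ug",
    "folate_dfe_ug",
    "folic_acid_ug",
    "vitb12_ug",
]

#: fortification vehicles and the recipe products that embed them
VEHICLES = ["cooking_oil", "wheat_flour", "maize_flour"]
WHEAT_PRODUCTS = ["bread", "buns_cakes_biscuits", "sweets"]
OIL_PRODUCTS = ["bread", "buns_cakes_biscuits", "sweets"]

UNITS = ["kg", "g", "L", "mL", "pieces"]
SOURCES = ["purchase", "own_production", "gift"]


@dataclass(frozen=True)
class FoodItem:
    """Static metadata for one food-list item (or composite component)."""

    code: str
    name: str
    group: str
    # composition per 100 g edible portion, in NUTRIENTS order
    comp: tuple[float, ...]
    source_fct: str = "KEN"
    refuse: float = 0.0
    density: float | None = None  # g/mL, liquids only
    portion_g: float | None = None  # grams per piece, pieces items only
    # unit -> probability; how the generator reports quantities
    unit_probs: dict[str, float] = field(default_factory=lambda: {"kg": 1.0})
    # (purchase, own_production, gift)
    source_probs: tuple[float, float, float] = (0.70, 0.25, 0.05)
    # national consumption model defaults: coverage probability and the
    # median consumption among consumers in grams per AFE per day
    # (as-reported, incl. refuse)
    coverage: float = 0.0
    median_g_afe_day: float = 0.0
    sdlog: float = 0.65
    # composite items: component code -> consumption-frequency weight
    components: dict[str, float] | None = None


def _c(e, fe, zn, rae, ret, dfe, fa, b12):
    return (e, fe, zn, rae, ret, dfe, fa, b12)


_Z = _c(0, 0, 0, 0, 0, 0, 0, 0)

# The 60-item survey food list. Coverage and median quantities are the
# national-level generator defaults; per-stratum adjustments live in
# hcesfort.synthetic.
FOOD_LIST: list[FoodItem] = [
    FoodItem("rice_husked", "Rice (husked)", "cereals", _c(360, 0.8, 1.2, 0, 0, 9, 0, 0),
             coverage=0.55, median_g_afe_day=100.0, sdlog=0.7),
    FoodItem("rice_paddy", "Rice (paddy)", "cereals", _c(340, 1.0, 1.4, 0, 0, 12, 0, 0),
             refuse=0.20, coverage=0.05, median_g_afe_day=71.4, sdlog=0.7,
             source_probs=(0.30, 0.65, 0.05)),
    FoodItem("maize_green_cob", "Maize (green, cob)", "cereals", _c(96, 0.8, 0.9, 9, 0, 38, 0, 0),
             refuse=0.45, portion_g=150.0, unit_probs={"pieces": 1.0},
             coverage=0.10, median_g_afe_day=57.1, sdlog=0.6, source_probs=(0.45, 0.50, 0.05)),
    FoodItem("maize_grain", "Maize (grain)", "cereals", _c(356, 2.7, 2.2, 6, 0, 25, 0, 0),
             coverage=0.22, median_g_afe_day=81.0, sdlog=0.75, source_probs=(0.35, 0.60, 0.05)),
    FoodItem("maize_flour", "Maize flour", "cereals", _c(362, 3.0, 1.6, 6, 0, 25, 0, 0),
             coverage=0.88, median_g_afe_day=250.0, sdlog=0.62, source_probs=(0.62, 0.33, 0.05)),
    FoodItem("millet_sorghum_grain", "Millet and sorghum (grain)", "cereals",
             _c(350, 3.0, 1.7, 0, 0, 20, 0, 0),
             coverage=0.06, median_g_afe_day=57.1, sdlog=0.7, source_probs=(0.40, 0.55, 0.05)),
    FoodItem("millet_sorghum_flour", "Millet and sorghum (flour)", "cereals",
             _c(355, 3.0, 1.8, 0, 0, 22, 0, 0),
             coverage=0.10, median_g_afe_day=61.9, sdlog=0.6, source_probs=(0.55, 0.40, 0.05)),
    FoodItem("wheat_flour", "Wheat flour", "cereals", _c(364, 1.2, 0.8, 0, 0, 26, 0, 0),
             coverage=0.15, median_g_afe_day=50.0, sdlog=0.7, source_probs=(0.98, 0.01, 0.01)),
    FoodItem("bread", "Bread", "cereals", _c(266, 1.1, 0.7, 0, 0, 24, 0, 0),
             coverage=0.30, median_g_afe_day=31.0, sdlog=0.65, source_probs=(0.97, 0.01, 0.02)),
    FoodItem("buns_cakes_biscuits", "Buns, cakes and biscuits", "cereals",
             _c(390, 1.0, 0.6, 0, 5, 20, 0, 0.05),
             coverage=0.13, median_g_afe_day=20.0, sdlog=0.6, source_probs=(0.96, 0.02, 0.02)),
    FoodItem("macaroni_spaghetti", "Macaroni and spaghetti", "cereals",
             _c(371, 1.3, 1.1, 0, 0, 18, 0, 0),
             coverage=0.05, median_g_afe_day=31.0, sdlog=0.6, source_probs=(0.99, 0.0, 0.01)),
    FoodItem("other_cereal_products", "Other cereal products", "cereals",
             _c(350, 1.5, 1.2, 0, 0, 20, 0, 0),
             coverage=0.04, median_g_afe_day=23.8, sdlog=0.6),
    FoodItem("cassava_fresh", "Cassava (fresh)", "roots", _c(160, 0.3, 0.3, 1, 0, 27, 0, 0),
             refuse=0.20, coverage=0.16, median_g_afe_day=114.3, sdlog=0.7,
             source_probs=(0.35, 0.60, 0.05)),
    FoodItem("cassava_flour", "Cassava (dry/flour)", "roots", _c(340, 1.9, 0.7, 1, 0, 30, 0, 0),
             coverage=0.12, median_g_afe_day=76.2, sdlog=0.7, source_probs=(0.50, 0.45, 0.05)),
    FoodItem("sweet_potatoes", "Sweet potatoes", "roots", _c(86, 0.6, 0.3, 4, 0, 11, 0, 0),
             refuse=0.15, coverage=0.24, median_g_afe_day=114.3, sdlog=0.7,
             source_probs=(0.40, 0.55, 0.05)),
    FoodItem("irish_potatoes", "Irish potatoes", "roots", _c(77, 0.8, 0.3, 0, 0, 15, 0, 0),
             refuse=0.10, coverage=0.16, median_g_afe_day=81.0, sdlog=0.65),
    FoodItem("yams_cocoyams", "Yams and cocoyams", "roots", _c(118, 0.5, 0.2, 7, 0, 23, 0, 0),
             refuse=0.15, coverage=0.04, median_g_afe_day=66.7, sdlog=0.65,
             source_probs=(0.40, 0.55, 0.05)),
    FoodItem("cooking_bananas", "Cooking bananas and plantains", "roots",
             _c(122, 0.6, 0.1, 56, 0, 22, 0, 0),
             refuse=0.35, coverage=0.14, median_g_afe_day=100.0, sdlog=0.7,
             source_probs=(0.45, 0.50, 0.05)),
    FoodItem("other_starches", "Other starches", "roots", _c(300, 0.8, 0.5, 0, 0, 15, 0, 0),
             coverage=0.03, median_g_afe_day=33.3, sdlog=0.6),
    FoodItem("sugar", "Sugar", "sugar", _c(387, 0.1, 0.0, 0, 0, 0, 0, 0),
             source_fct="USA", coverage=0.75, median_g_afe_day=40.5, sdlog=0.6,
             source_probs=(0.98, 0.01, 0.01)),
    FoodItem("sweets", "Sweets", "sugar", _c(420, 0.8, 0.4, 0, 3, 12, 0, 0),
             portion_g=25.0, unit_probs={"pieces": 1.0},
             coverage=0.08, median_g_afe_day=9.5, sdlog=0.55, source_probs=(0.99, 0.0, 0.01)),
    FoodItem("honey_syrup", "Honey, syrups and jams", "sugar", _c(304, 0.4, 0.2, 0, 0, 2, 0, 0),
             coverage=0.03, median_g_afe_day=16.7, sdlog=0.6),
    FoodItem("peas_beans_lentils", "Peas, beans and lentils (dry)", "pulses",
             _c(341, 5.0, 2.9, 1, 0, 400, 0, 0),
             coverage=0.70, median_g_afe_day=71.4, sdlog=0.55, source_probs=(0.55, 0.40, 0.05)),
    FoodItem("groundnuts", "Groundnuts (shelled)", "pulses", _c(567, 2.5, 3.3, 0, 0, 145, 0, 0),
             coverage=0.22, median_g_afe_day=28.6, sdlog=0.65, source_probs=(0.55, 0.40, 0.05)),
    FoodItem("coconut", "Coconut (mature/immature)", "pulses", _c(354, 2.4, 1.1, 0, 0, 26, 0, 0),
             refuse=0.50, coverage=0.18, median_g_afe_day=61.9, sdlog=0.65,
             source_probs=(0.60, 0.35, 0.05)),
    FoodItem("cashew_almonds", "Cashew, almonds and other nuts", "pulses",
             _c(553, 6.7, 5.8, 0, 0, 25, 0, 0),
             coverage=0.03, median_g_afe_day=14.3, sdlog=0.6),
    FoodItem("seeds_products", "Seeds and products from seeds", "pulses",
             _c(450, 5.0, 4.0, 2, 0, 60, 0, 0),
             coverage=0.03, median_g_afe_day=14.3, sdlog=0.6),
    # concatenated item: composition is the frequency-weighted mean of the
    # component foods (weights from a household-budget-survey fixture)
    FoodItem("onions_tomatoes_viungo", "Onions, tomatoes, carrots, peppers and other viungo",
             "vegetables", _Z, refuse=0.09,
             coverage=0.85, median_g_afe_day=61.9, sdlog=0.6, source_probs=(0.80, 0.17, 0.03),
             components={"c_onion": 0.35, "c_tomato": 0.40, "c_carrot": 0.12,
                         "c_green_pepper": 0.13}),
    FoodItem("greens_spinach", "Spinach, cabbage and other leafy greens", "vegetables",
             _c(36, 2.2, 0.5, 120, 0, 120, 0, 0),
             refuse=0.20, coverage=0.60, median_g_afe_day=81.0, sdlog=0.65,
             source_probs=(0.60, 0.36, 0.04)),
    FoodItem("other_vegetables", "Okra, brinjals and other vegetables", "vegetables",
             _c(33, 0.7, 0.6, 21, 0, 50, 0, 0),
             refuse=0.12, coverage=0.28, median_g_afe_day=52.4, sdlog=0.6,
             source_probs=(0.65, 0.31, 0.04)),
    FoodItem("dried_canned_vegetables", "Dried and canned vegetables", "vegetables",
             _c(260, 4.5, 2.0, 30, 0, 90, 0, 0),
             coverage=0.04, median_g_afe_day=14.3, sdlog=0.6),
    FoodItem("ripe_bananas", "Ripe bananas", "fruit", _c(89, 0.3, 0.2, 3, 0, 22, 0, 0),
             refuse=0.35, portion_g=120.0, unit_probs={"pieces": 1.0},
             coverage=0.20, median_g_afe_day=52.4, sdlog=0.6, source_probs=(0.60, 0.36, 0.04)),
    FoodItem("citrus_fruits", "Oranges and other citrus fruits", "fruit",
             _c(47, 0.1, 0.1, 1, 0, 17, 0, 0),
             refuse=0.30, coverage=0.14, median_g_afe_day=52.4, sdlog=0.6,
             source_probs=(0.65, 0.31, 0.04)),
    # concatenated fruit item
    FoodItem("mangoes_avocados_fruits", "Mangoes, avocados and other fruits", "fruit",
             _Z, refuse=0.30,
             coverage=0.18, median_g_afe_day=71.4, sdlog=0.65, source_probs=(0.55, 0.41, 0.04),
             components={"c_mango": 0.45, "c_avocado": 0.30, "c_papaya": 0.25}),
    FoodItem("sugarcane", "Sugarcane", "fruit", _c(58, 0.4, 0.1, 0, 0, 2, 0, 0),
             refuse=0.55, coverage=0.05, median_g_afe_day=71.4, sdlog=0.6,
             source_probs=(0.50, 0.46, 0.04)),
    FoodItem("beef", "Beef (including minced)", "meat", _c(217, 2.6, 4.8, 3, 3, 8, 0, 2.6),
             refuse=0.07, coverage=0.35, median_g_afe_day=42.9, sdlog=0.6,
             source_probs=(0.93, 0.05, 0.02)),
    FoodItem("goat_mutton", "Goat and mutton", "meat", _c(200, 2.8, 4.5, 0, 0, 5, 0, 2.4),
             refuse=0.10, coverage=0.09, median_g_afe_day=38.1, sdlog=0.6,
             source_probs=(0.80, 0.17, 0.03)),
    FoodItem("pork", "Pork", "meat", _c(250, 1.0, 2.4, 2, 2, 4, 0, 0.8),
             refuse=0.10, coverage=0.04, median_g_afe_day=33.3, sdlog=0.6),
    FoodItem("chicken_poultry", "Chicken and other poultry", "meat",
             _c(215, 1.3, 1.9, 16, 16, 6, 0, 0.4),
             refuse=0.25, portion_g=900.0, unit_probs={"pieces": 0.6, "kg": 0.4},
             coverage=0.12, median_g_afe_day=52.4, sdlog=0.55, source_probs=(0.60, 0.37, 0.03)),
    FoodItem("wild_birds_insects", "Wild birds and insects", "meat",
             _c(230, 5.0, 4.0, 0, 0, 10, 0, 1.5),
             coverage=0.02, median_g_afe_day=16.7, sdlog=0.6, source_probs=(0.30, 0.65, 0.05)),
    FoodItem("fresh_fish", "Fresh fish and shellfish", "fish", _c(110, 0.9, 0.7, 15, 15, 12, 0, 3.0),
             refuse=0.30, coverage=0.25, median_g_afe_day=61.9, sdlog=0.65,
             source_probs=(0.80, 0.17, 0.03)),
    FoodItem("dried_fish", "Dried and salted fish (incl. dagaa)", "fish",
             _c(290, 7.0, 3.5, 40, 40, 30, 0, 8.0),
             source_fct="WAF", coverage=0.34, median_g_afe_day=28.6, sdlog=0.55,
             source_probs=(0.90, 0.07, 0.03)),
    FoodItem("packaged_fish", "Packaged and canned fish", "fish",
             _c(190, 1.5, 1.0, 10, 10, 10, 0, 4.0),
             source_fct="USA", coverage=0.02, median_g_afe_day=16.7, sdlog=0.55,
             source_probs=(0.99, 0.0, 0.01)),
    FoodItem("eggs", "Eggs", "eggs", _c(143, 1.8, 1.3, 140, 140, 71, 0, 1.1),
             refuse=0.12, portion_g=50.0, unit_probs={"pieces": 1.0},
             coverage=0.20, median_g_afe_day=16.7, sdlog=0.55, source_probs=(0.75, 0.22, 0.03)),
    FoodItem("fresh_milk", "Fresh milk", "dairy", _c(64, 0.1, 0.4, 46, 46, 5, 0, 0.45),
             density=1.03, unit_probs={"L": 0.8, "mL": 0.2},
             coverage=0.27, median_g_afe_day=152.4, sdlog=0.7, source_probs=(0.65, 0.32, 0.03)),
    FoodItem("milk_products", "Milk products (fermented, cheese)", "dairy",
             _c(90, 0.1, 0.5, 40, 40, 8, 0, 0.5),
             coverage=0.05, median_g_afe_day=42.9, sdlog=0.6),
    FoodItem("canned_milk_powder", "Canned and powdered milk", "dairy",
             _c(490, 0.5, 3.3, 250, 250, 37, 0, 3.2),
             source_fct="USA", coverage=0.03, median_g_afe_day=16.7, sdlog=0.55,
             source_probs=(0.99, 0.0, 0.01)),
    FoodItem("cooking_oil", "Cooking oils", "fats", _c(884, 0.0, 0.0, 0, 0, 0, 0, 0),
             density=0.92, unit_probs={"L": 0.7, "mL": 0.3},
             coverage=0.91, median_g_afe_day=23.8, sdlog=0.60, source_probs=(1.0, 0.0, 0.0)),
    FoodItem("butter_margarine", "Butter, margarine and ghee", "fats",
             _c(717, 0.0, 0.1, 670, 670, 3, 0, 0.2),
             source_fct="USA", coverage=0.04, median_g_afe_day=11.9, sdlog=0.55,
             source_probs=(0.98, 0.01, 0.01)),
    FoodItem("salt", "Salt", "condiments", _Z, coverage=0.95, median_g_afe_day=9.5, sdlog=0.5,
             source_probs=(0.99, 0.0, 0.01)),
    FoodItem("other_spices", "Other spices and condiments", "condiments",
             _c(250, 4.0, 2.5, 30, 0, 60, 0, 0),
             coverage=0.30, median_g_afe_day=7.1, sdlog=0.6, source_probs=(0.90, 0.08, 0.02)),
    FoodItem("tea_leaves", "Tea (dry leaves)", "drinks", _c(0, 0, 0, 0, 0, 0, 0, 0),
             coverage=0.40, median_g_afe_day=2.9, sdlog=0.55, source_probs=(0.99, 0.0, 0.01)),
    FoodItem("coffee", "Coffee (ground or instant)", "drinks", _Z,
             coverage=0.05, median_g_afe_day=3.8, sdlog=0.55, source_probs=(0.98, 0.01, 0.01)),
    FoodItem("bottled_soft_drinks", "Bottled soft drinks", "drinks",
             _c(41, 0, 0, 0, 0, 0, 0, 0),
             density=1.04, unit_probs={"L": 1.0},
             coverage=0.15, median_g_afe_day=76.2, sdlog=0.6, source_probs=(1.0, 0.0, 0.0)),
    FoodItem("fruit_juices", "Canned and fresh fruit juices", "drinks",
             _c(45, 0.2, 0.0, 8, 0, 10, 0, 0),
             density=1.05, unit_probs={"L": 1.0},
             coverage=0.04, median_g_afe_day=52.4, sdlog=0.6, source_probs=(0.95, 0.04, 0.01)),
    FoodItem("local_brews", "Local brews", "drinks", _c(35, 0.4, 0.1, 1, 0, 4, 0, 0),
             density=1.01, unit_probs={"L": 1.0},
             coverage=0.08, median_g_afe_day=166.7, sdlog=0.7, source_probs=(0.75, 0.22, 0.03)),
    FoodItem("bottled_beer", "Bottled beer", "drinks", _c(43, 0.0, 0.0, 0, 0, 6, 0, 0.02),
             density=1.01, unit_probs={"L": 1.0},
             coverage=0.05, median_g_afe_day=104.8, sdlog=0.6, source_probs=(1.0, 0.0, 0.0)),
    FoodItem("wine_spirits", "Wine and spirits", "drinks", _c(230, 0.0, 0.0, 0, 0, 0, 0, 0),
             density=0.95, unit_probs={"L": 1.0},
             coverage=0.02, median_g_afe_day=33.3, sdlog=0.6, source_probs=(0.99, 0.0, 0.01)),
    FoodItem("prepared_meals", "Prepared tea, coffee and meals taken at home", "drinks",
             _c(120, 0.8, 0.6, 10, 2, 15, 0, 0.2),
             coverage=0.06, median_g_afe_day=66.7, sdlog=0.6, source_probs=(0.97, 0.01, 0.02)),
    FoodItem("other_foods", "Other foods not elsewhere classified", "other",
             _c(200, 1.0, 0.8, 5, 0, 15, 0, 0.1),
             coverage=0.03, median_g_afe_day=23.8, sdlog=0.6),
]

assert len(FOOD_LIST) == 60, "survey food module must have exactly 60 items"

#: component foods backing the concatenated items; never appear in the
#: consumption table themselves, only in the composition + weights fixtures
COMPONENT_FOODS: list[FoodItem] = [
    FoodItem("c_onion", "Onion", "vegetables", _c(40, 0.2, 0.2, 0, 0, 19, 0, 0), refuse=0.10),
    FoodItem("c_tomato", "Tomato", "vegetables", _c(18, 0.3, 0.2, 42, 0, 15, 0, 0), refuse=0.05),
    FoodItem("c_carrot", "Carrot", "vegetables", _c(41, 0.3, 0.2, 835, 0, 19, 0, 0), refuse=0.11),
    FoodItem("c_green_pepper", "Green pepper", "vegetables",
             _c(20, 0.3, 0.1, 18, 0, 10, 0, 0), refuse=0.18),
    FoodItem("c_mango", "Mango", "fruit", _c(60, 0.2, 0.1, 54, 0, 43, 0, 0), refuse=0.30),
    FoodItem("c_avocado", "Avocado", "fruit", _c(160, 0.6, 0.6, 7, 0, 81, 0, 0), refuse=0.26),
    FoodItem("c_papaya", "Papaya", "fruit", _c(43, 0.3, 0.1, 47, 0, 37, 0, 0), refuse=0.33),
]

#: recipe-ingredient mass fractions for the wheat/oil products
#: (product, ingredient, mass fraction of product weight)
RECIPES: list[tuple[str, str, float]] = [
    ("bread", "wheat_flour", 0.70),
    ("bread", "cooking_oil", 0.02),
    ("buns_cakes_biscuits", "wheat_flour", 0.55),
    ("buns_cakes_biscuits", "cooking_oil", 0.12),
    ("sweets", "wheat_flour", 0.40),
    ("sweets", "cooking_oil", 0.15),
]

FOOD_INDEX: dict[str, FoodItem] = {f.code: f for f in FOOD_LIST + COMPONENT_FOODS}
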